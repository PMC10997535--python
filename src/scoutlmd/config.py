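"""Structured run configuration (YAML) and provenance records.

A run config selects exactly one input mode — a file ``manifest`` of
per-patient NIfTI volumes, or a ``simulate`` block describing a synthetic
cohort — plus VOI parameters, dose constants and statistics options.  Every
physical constant of the dose model appears here with its standard default
and can be overridden.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, fields, replace

import yaml

from .dosimetry import CUMULATIVE_LIMIT_GY, SINGLE_TREATMENT_LIMIT_GY, DoseConstants
from .image_io import ImageGrid
from .phantom import CohortConfig, PhantomSpec
from .voi import DEFAULT_BODY_THRESHOLD_HU, DEFAULT_MARGIN_MM

__all__ = ["RunConfig", "PatientManifestEntry", "load_config", "config_hash", "write_provenance"]


class ConfigError(ValueError):
    """The run configuration is invalid."""


@dataclass(frozen=True)
class PatientManifestEntry:
    """One patient's files: label map, CT density, and the three scans."""

    patient_id: str
    labels: str
    density: str
    a_net_gbq: float
    scans: dict[str, str]  # role value -> NIfTI path

    def __post_init__(self) -> None:
        missing = {"maa_scout", "ho_scout", "ho_treatment"} - set(self.scans)
        if missing:
            raise ConfigError(
                f"patient {self.patient_id}: manifest missing scan roles {sorted(missing)}"
            )
        if self.a_net_gbq <= 0:
            raise ConfigError(f"patient {self.patient_id}: a_net_gbq must be > 0")


@dataclass(frozen=True)
class RunConfig:
    seed: int
    output_dir: str = "scoutlmd_out"
    manifest: tuple[PatientManifestEntry, ...] | None = None
    cohort: CohortConfig | None = None
    margin_mm: float = DEFAULT_MARGIN_MM
    threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU
    constants: DoseConstants = field(default_factory=DoseConstants)
    single_limit_gy: float = SINGLE_TREATMENT_LIMIT_GY
    cumulative_limit_gy: float = CUMULATIVE_LIMIT_GY
    zero_policy: str = "discard"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.cohort is None):
            raise ConfigError(
                "config must provide exactly one input mode: 'manifest' or 'simulate'"
            )
        if self.margin_mm < 0:
            raise ConfigError("margin_mm must be >= 0")
        if self.zero_policy not in ("discard", "pratt"):
            raise ConfigError(f"unknown zero_policy {self.zero_policy!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")


def _cohort_from_dict(block: dict) -> CohortConfig:
    block = dict(block)
    phantom_kwargs = {}
    if "grid" in block:
        g = block.pop("grid")
        phantom_kwargs["grid"] = ImageGrid(
            dims=tuple(g["dims"]),
            spacing_mm=tuple(g["spacing_mm"]),
            origin_mm=tuple(g.get("origin_mm", (0.0, 0.0, 0.0))),
        )
    if "fov_crop_fraction" in block:
        phantom_kwargs["fov_crop_fraction"] = block.pop("fov_crop_fraction")
    allowed = {f.name for f in fields(CohortConfig)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    cfg = CohortConfig(**block)
    if phantom_kwargs:
        cfg = replace(cfg, phantom=replace(cfg.phantom, **phantom_kwargs))
    return cfg


def _manifest_from_obj(obj, base_dir: str) -> tuple[PatientManifestEntry, ...]:
    if isinstance(obj, str):
        path = obj if os.path.isabs(obj) else os.path.join(base_dir, obj)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return _manifest_from_obj(data["patients"], os.path.dirname(os.path.abspath(path)))
    entries = []
    for item in obj:
        item = dict(item)
        for key in ("labels", "density"):
            if not os.path.isabs(item[key]):
                item[key] = os.path.join(base_dir, item[key])
        item["scans"] = {
            role: p if os.path.isabs(p) else os.path.join(base_dir, p)
            for role, p in item["scans"].items()
        }
        entries.append(
            PatientManifestEntry(
                patient_id=str(item["id"]),
                labels=item["labels"],
                density=item["density"],
                a_net_gbq=float(item["a_net_gbq"]),
                scans=item["scans"],
            )
        )
    return tuple(entries)


def load_config(path: str | os.PathLike, seed_override: int | None = None,
                output_dir_override: str | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Relative file paths in the manifest resolve against the config file's
    directory.  ``seed_override``/``output_dir_override`` implement the CLI
    flags of the same names.
    """
    path = os.fspath(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base_dir = os.path.dirname(os.path.abspath(path))

    if "seed" not in raw and seed_override is None:
        raise ConfigError("missing required key: seed")
    seed = int(seed_override if seed_override is not None else raw["seed"])

    kwargs: dict = {"seed": seed}
    if output_dir_override is not None:
        kwargs["output_dir"] = output_dir_override
    elif "output_dir" in raw:
        out = raw["output_dir"]
        kwargs["output_dir"] = out if os.path.isabs(out) else os.path.join(base_dir, out)

    if "manifest" in raw:
        kwargs["manifest"] = _manifest_from_obj(raw["manifest"], base_dir)
    if "simulate" in raw:
        kwargs["cohort"] = _cohort_from_dict(raw["simulate"] or {})

    voi_block = raw.get("voi", {})
    if "margin_mm" in voi_block:
        kwargs["margin_mm"] = float(voi_block["margin_mm"])
    if "threshold_hu" in voi_block:
        kwargs["threshold_hu"] = float(voi_block["threshold_hu"])

    dose_block = raw.get("dose", {})
    kwargs["constants"] = DoseConstants(
        k_e_j_per_gbq=float(dose_block.get("k_e_j_per_gbq", 15.87)),
        rho_lung_g_per_ml=float(dose_block.get("rho_lung_g_per_ml", 0.3)),
    )
    if "single_limit_gy" in dose_block:
        kwargs["single_limit_gy"] = float(dose_block["single_limit_gy"])
    if "cumulative_limit_gy" in dose_block:
        kwargs["cumulative_limit_gy"] = float(dose_block["cumulative_limit_gy"])

    stats_block = raw.get("stats", {})
    if "zero_policy" in stats_block:
        kwargs["zero_policy"] = stats_block["zero_policy"]
    if "alpha" in stats_block:
        kwargs["alpha"] = float(stats_block["alpha"])

    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable hash of every parameter that affects a run's outputs."""

    def _default(o):
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items()}
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps(config, default=_default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_provenance(config: RunConfig, out_dir: str, stage: str) -> str:
    """Record config hash, seed and package version next to a run's outputs."""
    from . import __version__

    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, f"provenance_{stage}.json")
    with open(path, "w") as fh:
        json.dump(
            {
                "stage": stage,
                "config_hash": config_hash(config),
                "seed": config.seed,
                "version": __version__,
            },
            fh,
            indent=2,
        )
    return path
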