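"""Synthetic torso phantoms and simulated scout/treatment scan triplets.

The generator exists so every pipeline stage can be exercised, with known
ground truth, in the absence of patient data.  Each digital patient is a set
of voxelized ellipsoid organs (body, liver, left lung, right lung) on a
common grid, plus three co-registered count images:

* a technetium-99m MAA scout scan,
* a holmium-166 scout scan,
* the posttreatment holmium-166 scan (the gold standard).

The activity model is a partition of the administered particles: a true
lung shunt fraction ``s`` lodges in the lungs (split between left and right
in proportion to their voxel counts, i.e. uniform lung concentration), and
the remainder stays in the liver.  MAA scans additionally receive two
phenomenological bias terms motivated by the known failure modes of MAA as
a surrogate particle — fragmentation of the albumin aggregates into
capillary-passing fragments (an extra apparent lung fraction ``f``) and
free pertechnetate circulating systemically (a diffuse whole-body
background fraction ``b``).  Neither is quantified in the literature at the
per-patient level; both are configuration-exposed fractions, not a physical
degradation model.

Imaging degradations are applied to the expected count image in order:
rigid misregistration shift (mm), Gaussian point-spread blur (FWHM in mm),
then Poisson sampling at a fixed total-count budget.  A field-of-view crop
can remove the superior lung slices from the scan volume, emulating the
narrow SPECT axial coverage that does not always include the upper lungs.

All randomness flows from one seed through named per-stage child streams
(geometry, scan parameters, noise), so each stage is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dosimetry import DoseConstants
from .image_io import (
    LABEL_AIR,
    LABEL_BODY,
    LABEL_LIVER,
    LABEL_LUNG_LEFT,
    LABEL_LUNG_RIGHT,
    ActivityImage,
    ImageGrid,
    LabelMap,
    ScalarVolume,
    ScanRole,
)

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "Phantom",
    "ScanModel",
    "PhantomTruth",
    "PhantomGeometryError",
    "make_phantom",
    "simulate_scan",
    "CohortConfig",
    "SimulatedPatient",
    "simulate_cohort",
    "DEFAULT_GRID",
]

#: Default simulation lattice: 96 x 96 x 72 voxels at 4 mm isotropic.
DEFAULT_GRID = ImageGrid(dims=(96, 96, 72), spacing_mm=(4.0, 4.0, 4.0))

# Hounsfield units assigned per tissue class in the synthetic CT.
HU_AIR = -1000.0
HU_LUNG = -800.0
HU_LIVER = 50.0
HU_BODY = 0.0


class PhantomGeometryError(ValueError):
    """The requested organ geometry violates the phantom invariants."""


@dataclass(frozen=True)
class Ellipsoid:
    """An axis-aligned ellipsoid in world (mm) coordinates."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be > 0")

    def contains(self, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semi_axes_mm
        return (
            ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2
        ) <= 1.0

    def jittered(self, rng: np.random.Generator, center_mm: float, scale: float) -> "Ellipsoid":
        """Randomly perturb centre (uniform +-center_mm) and semi-axes (uniform +-scale)."""
        c = tuple(v + rng.uniform(-center_mm, center_mm) for v in self.center_mm)
        s = tuple(v * (1.0 + rng.uniform(-scale, scale)) for v in self.semi_axes_mm)
        return Ellipsoid(c, s)


# Default torso geometry, mm.  The grid spans 384 x 384 x 288 mm with z the
# inferior->superior axis.  Lung volumes (~0.9-1.1 L each) and liver volume
# (~1.1 L) are adult-realistic; both lung bases sit ~6-16 mm above the liver
# dome so the 2 cm liver margin genuinely removes basal lung voxels, and
# every organ keeps a multi-voxel tissue shell to the body surface even
# after per-patient jitter (required for CT hole-filling to enclose them).
DEFAULT_BODY = Ellipsoid((192.0, 192.0, 144.0), (168.0, 130.0, 142.0))
DEFAULT_LIVER = Ellipsoid((170.0, 190.0, 78.0), (110.0, 62.0, 40.0))
DEFAULT_LUNG_LEFT = Ellipsoid((252.0, 192.0, 190.0), (50.0, 60.0, 70.0))
DEFAULT_LUNG_RIGHT = Ellipsoid((122.0, 192.0, 190.0), (58.0, 68.0, 66.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one digital patient.

    ``fov_crop_fraction`` removes that fraction of the superior lung extent
    (whole axial slices) from the scan volume; cropped voxels carry no
    labels and no recorded activity, as outside the imaged field of view.
    ``jitter_center_mm`` / ``jitter_scale`` control the per-patient random
    perturbation of organ geometry; defaults are small enough that organ
    disjointness is preserved for the default geometry.
    """

    grid: ImageGrid = DEFAULT_GRID
    body: Ellipsoid = DEFAULT_BODY
    liver: Ellipsoid = DEFAULT_LIVER
    lung_left: Ellipsoid = DEFAULT_LUNG_LEFT
    lung_right: Ellipsoid = DEFAULT_LUNG_RIGHT
    fov_crop_fraction: float = 0.0
    jitter_center_mm: float = 1.5
    jitter_scale: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.fov_crop_fraction <= 1.0:
            raise ValueError("fov_crop_fraction must be in [0, 1]")


@dataclass
class Phantom:
    """A rasterized phantom: scan-volume labels, full labels, and synthetic CT.

    ``labels`` reflects the imaged field of view (superior lung slices may
    be cropped); ``labels_full`` is the anatomical truth used for the true
    whole-lung mass.
    """

    spec: PhantomSpec
    labels: LabelMap
    labels_full: LabelMap
    density: ScalarVolume

    @property
    def grid(self) -> ImageGrid:
        return self.spec.grid


def _rasterize(spec: PhantomSpec, organs: dict[str, Ellipsoid]) -> np.ndarray:
    grid = spec.grid
    xs, ys, zs = grid.voxel_centers_mm()
    body = organs["body"].contains(xs, ys, zs)
    liver = organs["liver"].contains(xs, ys, zs)
    left = organs["lung_left"].contains(xs, ys, zs)
    right = organs["lung_right"].contains(xs, ys, zs)

    if (liver & left).any() or (liver & right).any() or (left & right).any():
        raise PhantomGeometryError("organ ellipsoids overlap after rasterization")
    air = ~body
    # interior = body voxels none of whose 6-neighbours are air; organs must
    # stay strictly interior so CT hole-filling encloses them in the contour
    touches_air = ndimage.binary_dilation(air, ndimage.generate_binary_structure(3, 1))
    for name, organ in (("liver", liver), ("lung_left", left), ("lung_right", right)):
        if not organ.any():
            raise PhantomGeometryError(f"{name} rasterizes to zero voxels")
        if (organ & air).any():
            raise PhantomGeometryError(f"{name} extends outside the body ellipsoid")
        if (organ & touches_air).any():
            raise PhantomGeometryError(f"{name} touches the body surface")

    labels = np.zeros(grid.dims, dtype=np.int16)
    labels[body] = LABEL_BODY
    labels[liver] = LABEL_LIVER
    labels[left] = LABEL_LUNG_LEFT
    labels[right] = LABEL_LUNG_RIGHT
    return labels


def _crop_plane_index(labels_full: np.ndarray, fov_crop_fraction: float) -> int | None:
    """First z slice outside the field of view, or None for no crop.

    The crop removes ``round(fraction * n)`` of the ``n`` axial slices that
    contain lung, counted from the superior end.
    """
    if fov_crop_fraction <= 0:
        return None
    lung = (labels_full == LABEL_LUNG_LEFT) | (labels_full == LABEL_LUNG_RIGHT)
    zs = np.nonzero(lung.any(axis=(0, 1)))[0]
    n_slices = len(zs)
    n_crop = int(round(fov_crop_fraction * n_slices))
    if n_crop == 0:
        return None
    return int(zs[-1]) - n_crop + 1


def make_phantom(spec: PhantomSpec, seed: int) -> Phantom:
    """Rasterize one phantom; deterministic for a fixed spec and seed.

    The seed drives the per-patient geometry jitter only.  Raises
    :class:`PhantomGeometryError` if the (jittered) organs overlap, fall
    outside the body, or vanish.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    organs = {
        "body": spec.body,
        "liver": spec.liver.jittered(rng, spec.jitter_center_mm, spec.jitter_scale),
        "lung_left": spec.lung_left.jittered(rng, spec.jitter_center_mm, spec.jitter_scale),
        "lung_right": spec.lung_right.jittered(rng, spec.jitter_center_mm, spec.jitter_scale),
    }
    labels_full = _rasterize(spec, organs)

    labels = labels_full.copy()
    z_cut = _crop_plane_index(labels_full, spec.fov_crop_fraction)
    if z_cut is not None:
        labels[:, :, z_cut:] = LABEL_AIR

    density = np.full(spec.grid.dims, HU_AIR)
    density[labels == LABEL_BODY] = HU_BODY
    density[labels == LABEL_LIVER] = HU_LIVER
    density[(labels == LABEL_LUNG_LEFT) | (labels == LABEL_LUNG_RIGHT)] = HU_LUNG

    return Phantom(
        spec=spec,
        labels=LabelMap(spec.grid, labels),
        labels_full=LabelMap(spec.grid, labels_full),
        density=ScalarVolume(spec.grid, density),
    )


@dataclass(frozen=True)
class ScanModel:
    """Activity-distribution and degradation parameters for one scan.

    ``shunt_fraction_s`` is the true fraction of particles lodging in the
    lungs; ``maa_fragmentation_f`` and ``maa_free_background_b`` are the
    MAA-only bias fractions (ignored for holmium roles).  The liver receives
    the remaining fraction, so the per-scan activity fractions partition 1.
    ``poisson=False`` returns the noiseless expected count image (useful for
    deterministic bias studies).
    """

    shunt_fraction_s: float
    maa_fragmentation_f: float = 0.0
    maa_free_background_b: float = 0.0
    psf_fwhm_mm: float = 0.0
    total_counts: int = 5_000_000
    misregistration_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    poisson: bool = True

    def __post_init__(self) -> None:
        for name in ("shunt_fraction_s", "maa_fragmentation_f", "maa_free_background_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.shunt_fraction_s + self.maa_fragmentation_f + self.maa_free_background_b > 1.0:
            raise ValueError("activity fractions s + f + b must not exceed 1")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.total_counts <= 0:
            raise ValueError("total_counts must be > 0")


@dataclass
class PhantomTruth:
    """Ground truth accompanying one simulated scan."""

    true_lmd_gy: float
    shunt_fraction_s: float
    effective_lung_fraction: float
    fractions: dict[str, float]
    lung_mass_both_kg: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"activity fractions must sum to 1, got {total}")


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def simulate_scan(
    phantom: Phantom,
    model: ScanModel,
    role: ScanRole,
    a_net_gbq: float,
    constants: DoseConstants = DoseConstants(),
) -> tuple[ActivityImage, PhantomTruth]:
    """Simulate one count image for a phantom.

    Expected activity is laid out on the *full* anatomy (uniform
    concentration over both lungs for the lung fraction, uniform over the
    liver for the remainder, uniform over the whole body for any MAA free
    background), slices outside the field of view are zeroed, and the
    degradations run shift -> blur -> Poisson.  The expected pre-crop,
    pre-noise total equals ``model.total_counts``.
    """
    role = ScanRole(role)
    grid = phantom.grid
    labels_full = phantom.labels_full.labels

    is_maa = role is ScanRole.MAA_SCOUT
    f = model.maa_fragmentation_f if is_maa else 0.0
    b = model.maa_free_background_b if is_maa else 0.0
    s = model.shunt_fraction_s
    lung_fraction = s + f
    liver_fraction = 1.0 - lung_fraction - b

    lungs = (labels_full == LABEL_LUNG_LEFT) | (labels_full == LABEL_LUNG_RIGHT)
    liver = labels_full == LABEL_LIVER
    body_all = labels_full != LABEL_AIR
    n_lungs = int(lungs.sum())
    n_liver = int(liver.sum())
    n_body = int(body_all.sum())
    if n_lungs == 0 or n_liver == 0:
        raise PhantomGeometryError("phantom has an empty lung or liver")

    total = float(model.total_counts)
    expected = np.zeros(grid.dims, dtype=np.float64)
    expected[lungs] += total * lung_fraction / n_lungs
    expected[liver] += total * liver_fraction / n_liver
    if b > 0:
        expected[body_all] += total * b / n_body

    z_cut = _crop_plane_index(labels_full, phantom.spec.fov_crop_fraction)
    if z_cut is not None:
        expected[:, :, z_cut:] = 0.0

    shift = np.asarray(model.misregistration_shift_mm, dtype=float)
    if np.any(shift != 0):
        shift_vox = shift / np.asarray(grid.spacing_mm)
        expected = ndimage.shift(expected, shift_vox, order=1, mode="constant", cval=0.0)
        np.clip(expected, 0.0, None, out=expected)
    if model.psf_fwhm_mm > 0:
        sigma_vox = model.psf_fwhm_mm * _FWHM_TO_SIGMA / np.asarray(grid.spacing_mm)
        expected = ndimage.gaussian_filter(expected, sigma_vox, mode="constant", cval=0.0)

    if model.poisson:
        rng = np.random.default_rng(np.random.SeedSequence(model.seed, spawn_key=(1,)))
        values = rng.poisson(expected).astype(np.float64)
    else:
        values = expected

    voxel_ml = grid.voxel_volume_ml
    lung_mass_both_kg = n_lungs * voxel_ml * constants.rho_lung_g_per_ml / 1000.0
    true_lmd = s * a_net_gbq * constants.k_e_j_per_gbq / lung_mass_both_kg
    truth = PhantomTruth(
        true_lmd_gy=true_lmd,
        shunt_fraction_s=s,
        effective_lung_fraction=lung_fraction,
        fractions={"lungs": lung_fraction, "liver": liver_fraction, "background": b},
        lung_mass_both_kg=lung_mass_both_kg,
    )
    image = ActivityImage(grid=grid, values=values, role=role, a_net_gbq=a_net_gbq)
    return image, truth


@dataclass(frozen=True)
class CohortConfig:
    """Distributional defaults for a simulated cohort.

    The true shunt fraction is zero-inflated: with probability ``p_zero``
    the patient has no shunt; otherwise ``s`` is log-normal (median
    ``s_median``, log-sd ``s_sigma_log``) capped at ``s_cap``.  MAA bias
    fractions ``f`` (fragmentation) and ``b`` (free background) are drawn
    per patient; net treatment activity spans the clinically typical
    2.2-12.9 GBq range with median ~6.2 GBq.  Degradations default to a
    12 mm FWHM point spread, 5e6 total counts, a per-scan random rigid
    shift with a 4 mm superior systematic component, and a random superior
    field-of-view crop.
    """

    n_patients: int = 37
    p_zero: float = 0.6
    s_median: float = 0.002
    s_sigma_log: float = 1.0
    s_cap: float = 0.2
    f_median: float = 0.004
    f_sigma_log: float = 1.2
    f_min: float = 5e-4
    f_max: float = 0.1
    b_min: float = 0.01
    b_max: float = 0.04
    a_net_median_gbq: float = 6.159
    a_net_sigma_log: float = 0.35
    a_net_min_gbq: float = 2.207
    a_net_max_gbq: float = 12.897
    psf_fwhm_mm: float = 12.0
    total_counts: int = 5_000_000
    shift_superior_mean_mm: float = 4.0
    shift_jitter_sd_mm: float = 1.5
    fov_crop_max: float = 0.35
    margin_mm: float = 20.0
    threshold_hu: float = -400.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ValueError("n_patients must be >= 3")
        if not 0.0 <= self.p_zero <= 1.0:
            raise ValueError("p_zero must be in [0, 1]")
        for name in ("s_median", "s_sigma_log", "f_median", "a_net_median_gbq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.fov_crop_max <= 1.0:
            raise ValueError("fov_crop_max must be in [0, 1]")


@dataclass
class SimulatedPatient:
    """One digital patient: phantom, three scans, truths, and parameters."""

    patient_id: str
    phantom: Phantom
    scans: dict[ScanRole, ActivityImage]
    truths: dict[ScanRole, PhantomTruth]
    a_net_gbq: float
    shunt_fraction_s: float
    maa_fragmentation_f: float
    maa_free_background_b: float


def _draw_lognormal(rng: np.random.Generator, median: float, sigma_log: float) -> float:
    return float(median * math.exp(rng.normal(0.0, sigma_log)))


def simulate_cohort(
    n_patients: int | None = None,
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
    constants: DoseConstants = DoseConstants(),
) -> list[SimulatedPatient]:
    """Simulate a cohort of digital patients, each with three co-registered scans.

    Fully reproducible from ``seed``: each patient draws its parameters and
    per-scan noise from dedicated child streams of one root seed sequence.
    ``n_patients`` overrides ``config.n_patients`` when given.
    """
    n = config.n_patients if n_patients is None else int(n_patients)
    if n < 3:
        raise ValueError("n_patients must be >= 3")
    root = np.random.SeedSequence(seed)
    patient_seeds = root.spawn(n)
    patients: list[SimulatedPatient] = []
    for i, pss in enumerate(patient_seeds):
        geom_ss, param_ss, noise_ss = pss.spawn(3)
        prng = np.random.default_rng(param_ss)

        if prng.uniform() < config.p_zero:
            s = 0.0
        else:
            s = min(_draw_lognormal(prng, config.s_median, config.s_sigma_log), config.s_cap)
        f = float(
            np.clip(
                _draw_lognormal(prng, config.f_median, config.f_sigma_log),
                config.f_min,
                config.f_max,
            )
        )
        b = float(prng.uniform(config.b_min, config.b_max))
        a_net = float(
            np.clip(
                _draw_lognormal(prng, config.a_net_median_gbq, config.a_net_sigma_log),
                config.a_net_min_gbq,
                config.a_net_max_gbq,
            )
        )
        crop = float(prng.uniform(0.0, config.fov_crop_max))
        spec = replace(config.phantom, fov_crop_fraction=crop)
        phantom = make_phantom(spec, seed=int(geom_ss.generate_state(1)[0] % (2**31)))

        scans: dict[ScanRole, ActivityImage] = {}
        truths: dict[ScanRole, PhantomTruth] = {}
        scan_noise_seeds = noise_ss.spawn(3)
        for role, nss in zip(
            (ScanRole.MAA_SCOUT, ScanRole.HO_SCOUT, ScanRole.HO_TREATMENT),
            scan_noise_seeds,
        ):
            shift = prng.normal(0.0, config.shift_jitter_sd_mm, size=3)
            shift[2] += config.shift_superior_mean_mm
            model = ScanModel(
                shunt_fraction_s=s,
                maa_fragmentation_f=f,
                maa_free_background_b=b,
                psf_fwhm_mm=config.psf_fwhm_mm,
                total_counts=config.total_counts,
                misregistration_shift_mm=tuple(shift),
                seed=int(nss.generate_state(1)[0] % (2**31)),
                poisson=config.poisson,
            )
            image, truth = simulate_scan(phantom, model, role, a_net, constants)
            scans[role] = image
            truths[role] = truth

        patients.append(
            SimulatedPatient(
                patient_id=f"P{i + 1:03d}",
                phantom=phantom,
                scans=scans,
                truths=truths,
                a_net_gbq=a_net,
                shunt_fraction_s=s,
                maa_fragmentation_f=f,
                maa_free_background_b=b,
            )
        )
    return patients
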