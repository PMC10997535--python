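"""Volumetric image I/O and the grid/label/activity data model.

All volumes in one patient's analysis live on a single shared voxel lattice
(:class:`ImageGrid`); the pipeline never resamples.  Scans must arrive
already co-registered — a grid mismatch is an error, not something to fix
silently, because interpolation would corrupt count totals.

Voxel indexing is 0-based.  World coordinates are millimetres, with the
centre of voxel ``(i, j, k)`` at ``origin + (i, j, k) * spacing``.  Activity
voxel values are treated as unitless relative counts: the dose formula uses
only count ratios, so no sensitivity or decay calibration is applied.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageGrid",
    "ScanRole",
    "ActivityImage",
    "LabelMap",
    "ScalarVolume",
    "LABEL_AIR",
    "LABEL_BODY",
    "LABEL_LIVER",
    "LABEL_LUNG_LEFT",
    "LABEL_LUNG_RIGHT",
    "LABEL_NAMES",
    "GridMismatchError",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "assert_same_grid",
]

# Fixed label vocabulary for organ maps.
LABEL_AIR = 0
LABEL_BODY = 1
LABEL_LIVER = 2
LABEL_LUNG_LEFT = 3
LABEL_LUNG_RIGHT = 4
LABEL_NAMES = {
    LABEL_AIR: "air",
    LABEL_BODY: "body",
    LABEL_LIVER: "liver",
    LABEL_LUNG_LEFT: "lung_left",
    LABEL_LUNG_RIGHT: "lung_right",
}


class GridMismatchError(ValueError):
    """Two volumes do not share a voxel lattice and cannot be compared."""


class VolumeFormatError(ValueError):
    """A file's contents violate the expected volume format."""


class ScanRole(enum.Enum):
    """Which of the three per-patient acquisitions an activity map represents."""

    MAA_SCOUT = "maa_scout"
    HO_SCOUT = "ho_scout"
    HO_TREATMENT = "ho_treatment"


@dataclass(frozen=True)
class ImageGrid:
    """Voxel lattice geometry shared by all images of one patient.

    Parameters
    ----------
    dims
        Number of voxels along each axis; each >= 1.
    spacing_mm
        Voxel pitch in mm along each axis; each > 0.
    origin_mm
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise ValueError("ImageGrid is strictly three-dimensional")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if any(d < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing_mm}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm^3); product of spacings / 1000."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def affine(self) -> np.ndarray:
        """4x4 axis-aligned NIfTI affine for this grid."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centres, broadcastable to the grid."""
        axes = [
            self.origin_mm[a] + np.arange(self.dims[a]) * self.spacing_mm[a]
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)


def assert_same_grid(a: ImageGrid, b: ImageGrid, tol_mm: float = 1e-3) -> None:
    """Raise :class:`GridMismatchError` unless ``a`` and ``b`` describe one lattice.

    Dimensions must match exactly; spacing and origin must agree within
    ``tol_mm`` per component.
    """
    if a.dims != b.dims:
        raise GridMismatchError(f"grid dims differ: {a.dims} vs {b.dims}")
    sp = np.abs(np.subtract(a.spacing_mm, b.spacing_mm))
    og = np.abs(np.subtract(a.origin_mm, b.origin_mm))
    if np.any(sp > tol_mm) or np.any(og > tol_mm):
        raise GridMismatchError(
            f"grid geometry differs beyond {tol_mm} mm: "
            f"spacing {a.spacing_mm} vs {b.spacing_mm}, origin {a.origin_mm} vs {b.origin_mm}"
        )


@dataclass
class ActivityImage:
    """Nonnegative voxel counts on a grid, tagged with scan role and activity.

    ``a_net_gbq`` is always the *net treatment* activity in GBq (calibrated
    treatment activity minus residual in the administration system), for all
    three scan roles: the scout scan contributes only its count ratio, which
    the dose formula scales by the treatment administration.
    """

    grid: ImageGrid
    values: np.ndarray
    role: ScanRole
    a_net_gbq: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if np.any(self.values < 0):
            raise VolumeFormatError("activity image contains negative voxel values")
        if not isinstance(self.role, ScanRole):
            self.role = ScanRole(self.role)
        self.a_net_gbq = float(self.a_net_gbq)
        if self.a_net_gbq <= 0:
            raise ValueError(f"a_net_gbq must be > 0, got {self.a_net_gbq}")

    @property
    def total_counts(self) -> float:
        return float(self.values.sum())


@dataclass
class LabelMap:
    """Integer organ labels on a grid, restricted to the fixed vocabulary."""

    grid: ImageGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.dims:
            raise ValueError(
                f"labels shape {self.labels.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = np.rint(self.labels).astype(np.int16)
            if np.any(np.abs(self.labels - as_int) > 1e-6):
                raise VolumeFormatError("label map contains non-integer values")
            self.labels = as_int
        self.labels = self.labels.astype(np.int16, copy=False)
        bad = np.setdiff1d(np.unique(self.labels), list(LABEL_NAMES))
        if bad.size:
            raise VolumeFormatError(
                f"label value outside vocabulary: {sorted(int(b) for b in bad)} "
                f"(allowed: {sorted(LABEL_NAMES)})"
            )

    def mask_of(self, *label_values: int) -> np.ndarray:
        """Boolean array of voxels carrying any of the given label values."""
        return np.isin(self.labels, label_values)

    def count(self, label_value: int) -> int:
        return int(np.count_nonzero(self.labels == label_value))


@dataclass
class ScalarVolume:
    """A plain real-valued volume (e.g. low-dose CT density in HU)."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )


def _grid_from_nifti(img: nib.Nifti1Image, path: str) -> ImageGrid:
    aff = img.affine
    rot = aff[:3, :3]
    spacing = np.abs(np.diag(rot))
    off_diag = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off_diag) > 1e-4 * max(spacing.max(), 1.0)):
        raise VolumeFormatError(
            f"{path}: oblique (non-axis-aligned) orientations are not supported; "
            "resample/reorient upstream"
        )
    if np.any(np.diag(rot) < 0):
        raise VolumeFormatError(
            f"{path}: negative axis directions are not supported; reorient upstream"
        )
    if img.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got {img.ndim}-D")
    return ImageGrid(
        dims=tuple(int(d) for d in img.shape),
        spacing_mm=tuple(float(s) for s in spacing),
        origin_mm=tuple(float(t) for t in aff[:3, 3]),
    )


def read_volume(
    path: str | os.PathLike,
    kind: str,
    *,
    role: ScanRole | str | None = None,
    a_net_gbq: float | None = None,
) -> ActivityImage | LabelMap | ScalarVolume:
    """Read a NIfTI volume as a typed object.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file.
    kind
        ``"activity"`` (requires ``role`` and ``a_net_gbq``), ``"labels"``,
        or ``"density"`` (HU volume for body contouring).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    grid = _grid_from_nifti(img, path)
    data = np.asarray(img.dataobj)
    if kind == "activity":
        if role is None or a_net_gbq is None:
            raise ValueError("kind='activity' requires role and a_net_gbq")
        return ActivityImage(grid=grid, values=data, role=ScanRole(role), a_net_gbq=a_net_gbq)
    if kind == "labels":
        return LabelMap(grid=grid, labels=data)
    if kind == "density":
        return ScalarVolume(grid=grid, values=data)
    raise ValueError(f"unknown kind {kind!r}; expected 'activity', 'labels' or 'density'")


def write_volume(path: str | os.PathLike, volume: ActivityImage | LabelMap | ScalarVolume) -> None:
    """Write a typed volume to NIfTI, preserving grid geometry in the affine."""
    path = os.fspath(path)
    if isinstance(volume, LabelMap):
        data = volume.labels.astype(np.int16)
    elif isinstance(volume, (ActivityImage, ScalarVolume)):
        data = volume.values.astype(np.float64)
    else:  # plain boolean mask arrays are handled by voi.write_mask
        raise TypeError(f"cannot write object of type {type(volume).__name__}")
    nib.save(nib.Nifti1Image(data, volume.grid.affine()), path)
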