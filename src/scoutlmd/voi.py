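"""Evaluation-region (VOI) construction.

Three regions drive the dose estimate:

* a **body contour** from threshold-based segmentation of the low-dose CT
  (largest connected component above a HU cut, interior holes filled) — the
  denominator region for total-body counts;
* the **liver plus a 3-D Euclidean margin** (default 2 cm), computed as a
  distance transform in millimetres so anisotropic voxels are respected;
* the **left-lung evaluation region**: the left-lung label voxels with every
  voxel inside liver+margin removed, suppressing spill-over of liver
  activity caused by misregistration, breathing and partial-volume blur.

Distances are voxel-centre to voxel-centre.  A voxel belongs to the dilated
mask iff the Euclidean mm distance from its centre to the nearest member
voxel centre is <= the margin.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import (
    LABEL_LIVER,
    LABEL_LUNG_LEFT,
    LABEL_LUNG_RIGHT,
    ImageGrid,
    LabelMap,
    ScalarVolume,
    assert_same_grid,
    write_volume,
)

__all__ = [
    "Mask",
    "VoiSet",
    "EmptyMaskError",
    "segment_body",
    "dilate_mask",
    "build_voi_set",
    "write_voi_set",
]

DEFAULT_MARGIN_MM = 20.0
DEFAULT_BODY_THRESHOLD_HU = -400.0


class EmptyMaskError(ValueError):
    """An operation received or produced a mask with no member voxels."""


@dataclass
class Mask:
    """Boolean voxel membership on a grid."""

    grid: ImageGrid
    members: np.ndarray

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=bool)
        if self.members.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.members.shape} does not match grid dims {self.grid.dims}"
            )

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.members))

    @property
    def volume_ml(self) -> float:
        return self.count * self.grid.voxel_volume_ml

    def __and__(self, other: "Mask") -> "Mask":
        assert_same_grid(self.grid, other.grid)
        return Mask(self.grid, self.members & other.members)


@dataclass
class VoiSet:
    """The evaluation masks for one patient.

    Invariants (enforced by :func:`build_voi_set`): ``liver`` is a subset of
    ``liver_plus_margin``; ``lung_left_eval`` and ``lung_right_eval`` are
    disjoint from ``liver_plus_margin`` and subsets of their lung labels.
    """

    body: Mask
    liver: Mask
    liver_plus_margin: Mask
    lung_left_eval: Mask
    lung_right_eval: Mask
    margin_mm: float


def segment_body(
    density: ScalarVolume,
    threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU,
) -> Mask:
    """Threshold-based body contour from a low-dose CT volume.

    Voxels with value >= ``threshold_hu`` are kept, reduced to the largest
    6-connected component, and interior holes (air-density lung cavities,
    bowel gas) are filled so that the body contour encloses all tissue.
    """
    above = density.values >= threshold_hu
    if not above.any():
        raise EmptyMaskError(f"empty body mask: no voxel >= {threshold_hu} HU")
    structure = ndimage.generate_binary_structure(3, 1)
    labeled, n = ndimage.label(above, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(above, labeled, index=np.arange(1, n + 1))
        above = labeled == (1 + int(np.argmax(sizes)))
    filled = ndimage.binary_fill_holes(above)
    return Mask(density.grid, filled)


def dilate_mask(mask: Mask, margin_mm: float) -> Mask:
    """Grow a mask by a Euclidean margin in millimetres.

    Returns the set of voxels whose centre lies within ``margin_mm`` of the
    nearest member voxel centre, computed with an exact Euclidean distance
    transform sampled at the grid spacing (so anisotropic voxels dilate
    correctly in physical units).  ``margin_mm == 0`` returns a copy of the
    input; the result is clipped to the grid by construction.
    """
    if margin_mm < 0:
        raise ValueError(f"margin_mm must be >= 0, got {margin_mm}")
    if mask.count == 0:
        raise EmptyMaskError("cannot dilate an empty mask")
    if margin_mm == 0:
        return Mask(mask.grid, mask.members.copy())
    dist = ndimage.distance_transform_edt(~mask.members, sampling=mask.grid.spacing_mm)
    return Mask(mask.grid, dist <= margin_mm)


def build_voi_set(
    labels: LabelMap,
    body: Mask,
    margin_mm: float = DEFAULT_MARGIN_MM,
) -> VoiSet:
    """Construct the full VOI set from an organ label map and a body contour.

    The liver is dilated by ``margin_mm`` (3-D Euclidean, in mm) and the
    dilated set is subtracted from each lung label to form the evaluation
    regions.  An empty left-lung evaluation region makes dose estimation
    impossible and raises :class:`EmptyMaskError`.
    """
    assert_same_grid(labels.grid, body.grid)
    liver = Mask(labels.grid, labels.mask_of(LABEL_LIVER))
    if liver.count > 0:
        liver_plus_margin = dilate_mask(liver, margin_mm)
    else:
        # No liver delineated: nothing to exclude.
        liver_plus_margin = Mask(labels.grid, np.zeros(labels.grid.dims, dtype=bool))
    lung_left = labels.mask_of(LABEL_LUNG_LEFT)
    lung_right = labels.mask_of(LABEL_LUNG_RIGHT)
    left_eval = Mask(labels.grid, lung_left & ~liver_plus_margin.members)
    right_eval = Mask(labels.grid, lung_right & ~liver_plus_margin.members)
    if left_eval.count == 0:
        raise EmptyMaskError(
            "left lung fully excluded: no left-lung voxel survives the "
            f"liver + {margin_mm:g} mm margin exclusion"
        )
    return VoiSet(
        body=body,
        liver=liver,
        liver_plus_margin=liver_plus_margin,
        lung_left_eval=left_eval,
        lung_right_eval=right_eval,
        margin_mm=float(margin_mm),
    )


def write_voi_set(vois: VoiSet, out_dir: str | os.PathLike, prefix: str = "voi") -> str:
    """Write each mask as a NIfTI binary volume plus a CSV summary.

    Returns the path of the summary CSV (columns: mask, voxels, volume_ml).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for name in ("body", "liver", "liver_plus_margin", "lung_left_eval", "lung_right_eval"):
        mask: Mask = getattr(vois, name)
        path = os.path.join(out_dir, f"{prefix}_{name}.nii.gz")
        lab = ScalarVolume(mask.grid, mask.members.astype(np.float64))
        write_volume(path, lab)
        rows.append({"mask": name, "voxels": mask.count, "volume_ml": f"{mask.volume_ml:.3f}"})
    summary = os.path.join(out_dir, f"{prefix}_summary.csv")
    with open(summary, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["mask", "voxels", "volume_ml"])
        writer.writeheader()
        writer.writerows(rows)
    return summary
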