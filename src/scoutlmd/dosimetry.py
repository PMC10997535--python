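"""Lung mean dose estimation from a count image and a VOI set.

The estimated lung mean dose (eLMD, in Gy) follows the standard SPECT/CT
count-ratio formalism restricted to the left lung, which is less prone to
erroneous capture of liver activity than the right:

    eLMD = (counts in left-lung VOI / counts in total body)
           * A_net [GBq] * k_E [J/GBq] / M_left-lung-VOI [kg]

with ``k_E = 15.87 J/GBq`` the energy-deposition conversion factor for the
holmium-166 administration and the left-lung VOI mass computed from its
volume at an assumed lung density of 0.3 g/mL.  ``A_net`` is the *net
treatment* activity for every scan role; a scout scan enters only through
its count ratio.  Dose to both lungs is assumed equal, so the left-lung
mean stands for the whole-lung mean.

Because only the count ratio enters, the estimate is invariant under global
rescaling of all voxel counts, making the quantitative units of the
reconstruction (counts vs Bq/mL) immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import ActivityImage, ScanRole, assert_same_grid
from .voi import EmptyMaskError, Mask, VoiSet

__all__ = [
    "DoseConstants",
    "DoseEstimate",
    "EligibilityDecision",
    "lung_mass_kg",
    "estimate_lmd_spect",
    "lsf_planar",
    "eligibility",
    "SINGLE_TREATMENT_LIMIT_GY",
    "CUMULATIVE_LIMIT_GY",
]

#: Lung dose limits used for radioembolization eligibility (Gy).
SINGLE_TREATMENT_LIMIT_GY = 30.0
CUMULATIVE_LIMIT_GY = 50.0


@dataclass(frozen=True)
class DoseConstants:
    """Physical constants of the dose model.

    ``k_e_j_per_gbq``: energy deposited in tissue per unit administered
    activity (J/GBq).  ``rho_lung_g_per_ml``: assumed uniform lung density.
    """

    k_e_j_per_gbq: float = 15.87
    rho_lung_g_per_ml: float = 0.3

    def __post_init__(self) -> None:
        if self.k_e_j_per_gbq <= 0:
            raise ValueError("k_e_j_per_gbq must be > 0")
        if self.rho_lung_g_per_ml <= 0:
            raise ValueError("rho_lung_g_per_ml must be > 0")


@dataclass
class DoseEstimate:
    """An eLMD value together with every intermediate it was computed from.

    The invariant ``elmd_gy == shunt_ratio * a_net_gbq * k_e / mass`` makes
    the estimate recomputable from its own fields.
    """

    elmd_gy: float
    counts_left_lung: float
    counts_total_body: float
    shunt_ratio: float
    mass_left_lung_kg: float
    a_net_gbq: float
    scan_role: ScanRole


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    rule: str


def lung_mass_kg(voi: Mask, rho_lung_g_per_ml: float = 0.3) -> float:
    """Mass (kg) of a lung VOI: voxel count x voxel volume (mL) x density / 1000."""
    if rho_lung_g_per_ml <= 0:
        raise ValueError("rho_lung_g_per_ml must be > 0")
    if voi.count == 0:
        raise EmptyMaskError("cannot compute lung mass of an empty VOI")
    return voi.count * voi.grid.voxel_volume_ml * rho_lung_g_per_ml / 1000.0


def estimate_lmd_spect(
    activity: ActivityImage,
    vois: VoiSet,
    constants: DoseConstants = DoseConstants(),
) -> DoseEstimate:
    """Estimate the lung mean dose from one SPECT count image and the VOI set.

    Numerator counts are summed over the left-lung evaluation region (left
    lung minus liver + margin); denominator counts over the CT-derived body
    contour.  The VOI mass in the formula is the mass of the same left-lung
    evaluation region.
    """
    assert_same_grid(activity.grid, vois.body.grid)
    if vois.lung_left_eval.count == 0:
        raise EmptyMaskError("left-lung evaluation region is empty")
    counts_left = float(activity.values[vois.lung_left_eval.members].sum())
    counts_body = float(activity.values[vois.body.members].sum())
    if counts_body <= 0:
        raise ValueError("zero total-body counts: not a valid scan")
    mass_kg = lung_mass_kg(vois.lung_left_eval, constants.rho_lung_g_per_ml)
    ratio = counts_left / counts_body
    elmd = ratio * activity.a_net_gbq * constants.k_e_j_per_gbq / mass_kg
    return DoseEstimate(
        elmd_gy=elmd,
        counts_left_lung=counts_left,
        counts_total_body=counts_body,
        shunt_ratio=ratio,
        mass_left_lung_kg=mass_kg,
        a_net_gbq=activity.a_net_gbq,
        scan_role=activity.role,
    )


def lsf_planar(activity: ActivityImage, lung_mask: Mask, liver_mask: Mask) -> float:
    """Planar-style lung shunt fraction: lung counts / (lung + liver counts).

    This is the conventional two-region estimator used with planar
    scintigraphy; it is provided for comparison with the volumetric ratio.
    """
    assert_same_grid(lung_mask.grid, liver_mask.grid)
    assert_same_grid(activity.grid, lung_mask.grid)
    if np.any(lung_mask.members & liver_mask.members):
        raise ValueError("lung and liver masks must be disjoint")
    lung = float(activity.values[lung_mask.members].sum())
    liver = float(activity.values[liver_mask.members].sum())
    total = lung + liver
    if total <= 0:
        raise ValueError("zero combined lung+liver counts")
    return lung / total


def eligibility(
    elmd_gy: float,
    prior_lung_dose_gy: float = 0.0,
    single_limit_gy: float = SINGLE_TREATMENT_LIMIT_GY,
    cumulative_limit_gy: float = CUMULATIVE_LIMIT_GY,
) -> EligibilityDecision:
    """Radioembolization lung-dose eligibility.

    A patient is eligible iff the predicted dose does not exceed the
    single-treatment limit (default 30 Gy) and the cumulative lung dose over
    all treatments does not exceed the multiple-treatment limit (default
    50 Gy).
    """
    if elmd_gy < 0 or prior_lung_dose_gy < 0:
        raise ValueError("doses must be >= 0")
    if elmd_gy > single_limit_gy:
        return EligibilityDecision(False, f"single-treatment {single_limit_gy:g} Gy")
    if elmd_gy + prior_lung_dose_gy > cumulative_limit_gy:
        return EligibilityDecision(False, f"cumulative {cumulative_limit_gy:g} Gy")
    return EligibilityDecision(True, "within limits")
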