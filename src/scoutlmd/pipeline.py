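"""End-to-end wiring: phantom or file inputs -> VOIs -> dose -> records."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dosimetry import DoseConstants, DoseEstimate, eligibility, estimate_lmd_spect
from .image_io import ActivityImage, LabelMap, ScalarVolume, ScanRole
from .phantom import SimulatedPatient
from .stats import PatientRecord
from .voi import (
    DEFAULT_BODY_THRESHOLD_HU,
    DEFAULT_MARGIN_MM,
    VoiSet,
    build_voi_set,
    segment_body,
)

__all__ = ["PatientDoses", "estimate_patient", "cohort_records", "doses_dataframe"]


@dataclass
class PatientDoses:
    """All three per-scan dose estimates for one patient, plus the VOI set."""

    patient_id: str
    vois: VoiSet
    estimates: dict[ScanRole, DoseEstimate]

    def record(self) -> PatientRecord:
        return PatientRecord(
            patient_id=self.patient_id,
            elmd_maa_gy=self.estimates[ScanRole.MAA_SCOUT].elmd_gy,
            elmd_ho_scout_gy=self.estimates[ScanRole.HO_SCOUT].elmd_gy,
            lmd_ho_treatment_gy=self.estimates[ScanRole.HO_TREATMENT].elmd_gy,
        )


def estimate_patient(
    patient_id: str,
    labels: LabelMap,
    density: ScalarVolume,
    scans: dict[ScanRole, ActivityImage],
    margin_mm: float = DEFAULT_MARGIN_MM,
    threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU,
    constants: DoseConstants = DoseConstants(),
) -> PatientDoses:
    """Build the VOI set once per patient and estimate every scan's dose."""
    body = segment_body(density, threshold_hu)
    vois = build_voi_set(labels, body, margin_mm)
    estimates = {role: estimate_lmd_spect(img, vois, constants) for role, img in scans.items()}
    return PatientDoses(patient_id=patient_id, vois=vois, estimates=estimates)


def cohort_records(
    patients: list[SimulatedPatient],
    margin_mm: float = DEFAULT_MARGIN_MM,
    threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU,
    constants: DoseConstants = DoseConstants(),
) -> tuple[list[PatientRecord], list[PatientDoses]]:
    """Run the full estimation pipeline over a simulated cohort."""
    doses = [
        estimate_patient(
            p.patient_id, p.phantom.labels, p.phantom.density, p.scans,
            margin_mm, threshold_hu, constants,
        )
        for p in patients
    ]
    return [d.record() for d in doses], doses


def doses_dataframe(doses: list[PatientDoses]) -> pd.DataFrame:
    """One CSV-ready row per scan with every dose-estimate field."""
    rows = []
    for pd_ in doses:
        for role, est in pd_.estimates.items():
            rows.append(
                {
                    "patient_id": pd_.patient_id,
                    "scan_role": role.value,
                    "counts_left_lung": est.counts_left_lung,
                    "counts_total_body": est.counts_total_body,
                    "shunt_ratio": est.shunt_ratio,
                    "mass_left_lung_kg": est.mass_left_lung_kg,
                    "a_net_gbq": est.a_net_gbq,
                    "elmd_gy": round(est.elmd_gy, 2),
                    "eligible": eligibility(est.elmd_gy).eligible,
                }
            )
    return pd.DataFrame(rows)
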