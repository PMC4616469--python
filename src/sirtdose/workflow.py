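"""End-to-end measurement of synthetic cases and cohort dose tables.

Bridges phantom output to the dosimetry input: measures the three liver
VOIs on each modality's volume, derives the lung shunt fraction from the
planar pair (planning arm) or from extrapolated basal-lung counts
(post-treatment PET arm), and assembles the per-case paired dose table the
statistical comparison consumes.
"""

from __future__ import annotations

import pandas as pd

from .compartments import COMPARTMENTS, IN_TARGET, LIVER_PARTITIONS, LUNG, OUT_TARGET, TUMOR
from .dosimetry import PartitionMeasurements, dose_report
from .phantom import SyntheticCase
from .quantify import (
    basal_lung_concentration,
    extrapolate_lung_counts,
    lsf_from_pet,
    lung_shunt_fraction,
    measure_voi,
    planar_liver_mask,
    planar_roi_mask,
    roi_counts,
)


def measure_maa(case: SyntheticCase, roi_margin_px: int = 3) -> PartitionMeasurements:
    """Planning-arm measurements: SPECT VOIs plus planar-scintigraphy LSF."""
    img = case.maa_volume
    if img is None or case.planar_anterior is None:
        raise ValueError("case was generated without rendered MAA images")
    vois = {c: measure_voi(img, c) for c in LIVER_PARTITIONS}
    lung_voi = measure_voi(img, LUNG)
    lung_mask = planar_roi_mask(img.labels, LUNG, margin_px=roi_margin_px)
    liver_mask = planar_liver_mask(img.labels, margin_px=roi_margin_px)
    lsf = lung_shunt_fraction(
        roi_counts(case.planar_anterior, case.planar_posterior, lung_mask),
        roi_counts(case.planar_anterior, case.planar_posterior, liver_mask),
    )
    return PartitionMeasurements(
        tumor=vois[TUMOR],
        in_target=vois[IN_TARGET],
        out_target=vois[OUT_TARGET],
        lung_total_counts=lung_voi.total_counts,
        lsf=lsf,
        lung_volume_ml=lung_voi.volume_ml,
    )


def measure_pet(case: SyntheticCase) -> PartitionMeasurements:
    """Post-treatment measurements: PET VOIs with basal-lung extrapolation.

    The lung volume comes from the label grid (the CT-segmentation
    analogue); total lung counts are extrapolated from the mean
    concentration of the basal lungs inside the field of view.
    """
    img = case.pet_volume
    if img is None:
        raise ValueError("case was generated without a rendered PET volume")
    vois = {c: measure_voi(img, c) for c in LIVER_PARTITIONS}
    lung_volume_ml = measure_voi(img, LUNG).volume_ml
    lung_total = extrapolate_lung_counts(basal_lung_concentration(img), lung_volume_ml)
    lsf = lsf_from_pet(lung_total, vois.values())
    return PartitionMeasurements(
        tumor=vois[TUMOR],
        in_target=vois[IN_TARGET],
        out_target=vois[OUT_TARGET],
        lung_total_counts=lung_total,
        lsf=lsf,
        lung_volume_ml=lung_volume_ml,
    )


def case_dose_row(case: SyntheticCase) -> dict:
    """Paired MAA/PET dose report for one case, as one flat table row."""
    m_maa = measure_maa(case)
    m_pet = measure_pet(case)
    rep_maa = dose_report(case.truth.injected_gbq, m_maa)
    rep_pet = dose_report(case.truth.injected_gbq, m_pet)
    row = {
        "case": case.case_id,
        "injected_gbq": case.truth.injected_gbq,
        "lsf_maa": m_maa.lsf,
        "lsf_pet": m_pet.lsf,
        "lsf_true": case.truth.lsf_true,
    }
    for comp in COMPARTMENTS:
        row[f"dose_maa_{comp}"] = rep_maa.absorbed_dose_gy[comp]
        row[f"dose_pet_{comp}"] = rep_pet.absorbed_dose_gy[comp]
        row[f"dose_true_{comp}"] = case.truth.doses_gy[comp]
    return row


def cohort_dose_table(cases: list[SyntheticCase]) -> pd.DataFrame:
    """Paired dose table for a rendered cohort (one row per case)."""
    return pd.DataFrame([case_dose_row(c) for c in cases])
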