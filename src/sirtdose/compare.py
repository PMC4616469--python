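"""Paired modality comparison and cohort-level statistical report.

The study design compares, within patients, dosimetry derived from the
planning ⁹⁹ᵐTc-MAA scan against dosimetry derived from the post-treatment
⁹⁰Y PET/CT: paired t tests on per-compartment doses and on the lung shunt
fraction, Pearson correlation between the two modalities, and
progression-free survival stratified by the PET tumor dose (log-rank).
All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import COMPARTMENTS, TUMOR
from .survival import (
    SurvivalRecord,
    dichotomize_by_dose,
    km_estimate,
    logrank_test,
)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    mean_difference: float
    degenerate: bool = False


def paired_t_test(x, y) -> PairedTestResult:
    """Classical paired Student t test on within-case differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = y - x
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return PairedTestResult(0.0, 1.0, 0.0, degenerate=True)
        return PairedTestResult(np.inf, 0.0, float(d.mean()), degenerate=True)
    res = stats.ttest_rel(y, x)
    return PairedTestResult(float(res.statistic), float(res.pvalue), float(d.mean()))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float


def pearson_r(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue))


def chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (no continuity correction by default)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be >= 0")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate margins: a row or column sums to zero")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=correction)
    return float(chi2), float(p)


def run_comparison(
    dose_table: pd.DataFrame,
    survival: list[SurvivalRecord] | None = None,
    dose_threshold_gy: float = 200.0,
) -> dict:
    """Full cohort report: paired tests, correlations, and stratified PFS.

    ``dose_table`` needs one row per case with columns ``case``,
    ``lsf_maa``, ``lsf_pet`` and ``dose_maa_<c>``/``dose_pet_<c>`` for each
    compartment ``c``. If ``survival`` is given, cases are dichotomized by
    the PET tumor dose at ``dose_threshold_gy`` and compared by log-rank.
    """
    report: dict = {"n_cases": int(len(dose_table)), "compartments": {}}
    for comp in COMPARTMENTS:
        maa = dose_table[f"dose_maa_{comp}"].to_numpy()
        pet = dose_table[f"dose_pet_{comp}"].to_numpy()
        entry = {
            "mean_maa": float(maa.mean()),
            "mean_pet": float(pet.mean()),
            "mean_difference_maa_minus_pet": float((maa - pet).mean()),
        }
        if len(dose_table) >= 2:
            t = paired_t_test(pet, maa)  # difference = maa - pet
            entry["paired_t"] = {"t": t.statistic, "p": t.p_value, "degenerate": t.degenerate}
        if len(dose_table) >= 3 and np.std(maa) > 0 and np.std(pet) > 0:
            c = pearson_r(maa, pet)
            entry["pearson"] = {"r": c.r, "p": c.p_value}
        report["compartments"][comp] = entry

    lsf_maa = dose_table["lsf_maa"].to_numpy()
    lsf_pet = dose_table["lsf_pet"].to_numpy()
    lsf_entry = {
        "mean_maa": float(lsf_maa.mean()),
        "mean_pet": float(lsf_pet.mean()),
        "mean_difference_maa_minus_pet": float((lsf_maa - lsf_pet).mean()),
    }
    if len(dose_table) >= 2:
        t = paired_t_test(lsf_pet, lsf_maa)
        lsf_entry["paired_t"] = {"t": t.statistic, "p": t.p_value, "degenerate": t.degenerate}
    report["lsf"] = lsf_entry

    if survival is not None:
        groups = dichotomize_by_dose(
            dose_table[f"dose_pet_{TUMOR}"].to_numpy(), dose_threshold_gy
        )
        by_group = {"high": [], "low": []}
        for rec, g in zip(survival, groups):
            by_group[g].append(rec)
        surv_entry: dict = {
            "threshold_gy": dose_threshold_gy,
            "n_high": len(by_group["high"]),
            "n_low": len(by_group["low"]),
        }
        for g, recs in by_group.items():
            if recs:
                km = km_estimate(recs)
                surv_entry[f"km_{g}"] = {
                    "restricted_mean_days": km.restricted_mean,
                    "restricted_mean_se_days": km.restricted_mean_se,
                    "median_days": km.median,
                }
        if by_group["high"] and by_group["low"]:
            lr = logrank_test(by_group["high"], by_group["low"])
            surv_entry["logrank"] = {
                "chi2": lr.chi2,
                "p": lr.p_value,
                "degenerate": lr.degenerate,
            }
        report["survival"] = surv_entry
    return report
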