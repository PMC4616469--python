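"""Kaplan–Meier estimation, dose-group dichotomization and the log-rank test.

Thin, typed wrappers over lifelines that return plain results the rest of
the pipeline (and its tests) can assert on: the product-limit step
function, a restricted mean with Greenwood-based standard error over the
observed horizon, the median (None when the curve never reaches 0.5), and
the standard 1-df two-group log-rank statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.integrate
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time


@dataclass(frozen=True)
class SurvivalRecord:
    """One progression-free-survival observation."""

    time_days: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError(f"time must be > 0, got {self.time_days}")


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate with summary statistics."""

    times: np.ndarray          # event/censoring timeline
    survival: np.ndarray       # S(t) at those times
    restricted_mean: float     # mean survival restricted to the horizon
    restricted_mean_se: float  # Greenwood-based SE of the restricted mean
    median: float | None       # first t with S(t) <= 0.5, None if never
    horizon: float

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def dichotomize_by_dose(doses_gy: Sequence[float], threshold_gy: float) -> list[str]:
    """Label each case ``"high"`` if dose > threshold (strict), else ``"low"``."""
    if threshold_gy <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold_gy}")
    return ["high" if d > threshold_gy else "low" for d in doses_gy]


def km_estimate(
    records: Iterable[SurvivalRecord], horizon: float | None = None
) -> KMEstimate:
    """Kaplan–Meier estimate for one group of survival records."""
    records = list(records)
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time_days for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter().fit(times, events)
    horizon = float(horizon if horizon is not None else times.max())
    with warnings.catch_warnings():
        # quadrature of the step function hits the subdivision cap; harmless
        warnings.simplefilter("ignore", scipy.integrate.IntegrationWarning)
        rm, rm_var = restricted_mean_survival_time(kmf, t=horizon, return_variance=True)
    sf = kmf.survival_function_
    timeline = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    below = timeline[surv <= 0.5]
    median = float(below[0]) if below.size else None
    return KMEstimate(
        times=timeline,
        survival=surv,
        restricted_mean=float(rm),
        restricted_mean_se=float(np.sqrt(max(rm_var, 0.0))),
        median=median,
        horizon=horizon,
    )


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p_value: float
    degenerate: bool = False


def logrank_test(
    group_a: Iterable[SurvivalRecord], group_b: Iterable[SurvivalRecord]
) -> LogrankResult:
    """Two-group log-rank test (1 df, hypergeometric variance)."""
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in a + b):
        return LogrankResult(chi2=0.0, p_value=1.0, degenerate=True)
    res = _ll_logrank(
        [r.time_days for r in a],
        [r.time_days for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    return LogrankResult(chi2=float(res.test_statistic), p_value=float(res.p_value))


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Survival records as a tidy DataFrame (time_days, event, group)."""
    return pd.DataFrame(
        [
            {"time_days": r.time_days, "event": int(r.event), "group": r.group}
            for r in records
        ]
    )
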