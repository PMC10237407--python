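"""Feasibility design and trial analyses.

Covers the statistics the feasibility study needs: exact (Clopper-Pearson)
one-sided binomial upper confidence limits for the population non-adherence
rate, per-fraction adherence assessment against the primary-endpoint time
windows (TID fractions within 1 h of schedule, QD fractions within 24 h),
Kaplan-Meier survival estimation, Welch t-tests on per-patient
time-to-progression ratios against an external control arm, and median
imputation of missing covariates.  Multivariable Cox and logistic model
fits are deliberately left to general-purpose statistics packages; this
module prepares their inputs (including the tumor BED covariate at
alpha/beta = 10 Gy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from . import bed as _bed

#: Primary-endpoint tolerance windows, hours.
TID_WINDOW_H = 1.0
QD_WINDOW_H = 24.0


class TrialStatsError(ValueError):
    """Invalid input to a trial statistic."""


def exact_binomial_upper(failures: int, n: int, confidence: float = 0.95) -> float:
    """One-sided Clopper-Pearson upper confidence limit on a failure rate.

    The smallest p with P(X <= failures | n, p) <= 1 - confidence, i.e. the
    ``confidence`` quantile of Beta(failures + 1, n - failures); equals 1
    when every trial failed.
    """
    if n < 1 or not 0 <= failures <= n:
        raise TrialStatsError(f"invalid counts failures={failures}, n={n}")
    if not 0.0 < confidence < 1.0:
        raise TrialStatsError(f"confidence must lie in (0, 1), got {confidence}")
    if failures == n:
        return 1.0
    return float(stats.beta.ppf(confidence, failures + 1, n - failures))


@dataclass(frozen=True)
class AdherenceRecord:
    """One fraction: planned vs. actual administration time (absolute hours)."""

    planned_h: float
    actual_h: Optional[float]  # None = fraction missed / not recorded
    phase_kind: str  # "QD" or "TID"

    def __post_init__(self) -> None:
        if self.phase_kind not in ("QD", "TID"):
            raise TrialStatsError(f"phase kind must be 'QD' or 'TID', got {self.phase_kind}")


@dataclass(frozen=True)
class FractionCompliance:
    planned_h: float
    actual_h: Optional[float]
    phase_kind: str
    compliant: bool
    missing: bool
    deviation_h: Optional[float]


@dataclass(frozen=True)
class AdherenceAssessment:
    """Per-fraction compliance plus the overall completion flag."""

    fractions: tuple[FractionCompliance, ...]
    completed: bool

    @property
    def n_compliant(self) -> int:
        return sum(f.compliant for f in self.fractions)


def assess_adherence(log: Sequence[AdherenceRecord]) -> AdherenceAssessment:
    """Evaluate a patient's log against the primary-endpoint windows.

    A TID fraction is compliant iff |actual - planned| <= 1 h, a QD fraction
    iff |actual - planned| <= 24 h; a missing actual time is non-compliant.
    The course is completed iff every fraction is compliant.  The result is
    invariant to record order (records are sorted by planned time).
    """
    if not log:
        raise TrialStatsError("empty adherence log")
    records = sorted(log, key=lambda r: r.planned_h)
    planned = [r.planned_h for r in records]
    if any(b <= a for a, b in zip(planned, planned[1:])):
        raise TrialStatsError("planned times must be strictly increasing")
    out = []
    for r in records:
        if r.actual_h is None:
            out.append(
                FractionCompliance(r.planned_h, None, r.phase_kind, False, True, None)
            )
            continue
        dev = r.actual_h - r.planned_h
        window = TID_WINDOW_H if r.phase_kind == "TID" else QD_WINDOW_H
        out.append(
            FractionCompliance(
                r.planned_h, r.actual_h, r.phase_kind, abs(dev) <= window, False, dev
            )
        )
    return AdherenceAssessment(fractions=tuple(out), completed=all(f.compliant for f in out))


@dataclass(frozen=True)
class SurvivalRecord:
    """A right-censored survival observation (time in months)."""

    time: float
    event: bool  # True = progression/death observed

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise TrialStatsError(f"survival time must be positive, got {self.time}")


@dataclass(frozen=True)
class KMResult:
    """Product-limit estimate: step function plus the median."""

    times: np.ndarray  # event/censoring times (step-function support)
    survival: np.ndarray  # S(t) at each time
    median: Optional[float]  # earliest t with S(t) <= 0.5; None if not reached
    median_reached: bool

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord]) -> KMResult:
    """Kaplan-Meier product-limit estimator (via lifelines)."""
    if not records:
        raise TrialStatsError("at least one survival record required")
    durations = [r.time for r in records]
    events = [r.event for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    reached = math.isfinite(median)
    return KMResult(
        times=times,
        survival=surv,
        median=median if reached else None,
        median_reached=reached,
    )


@dataclass(frozen=True)
class TTPRecord:
    """Per-patient times to progression on the current vs. a reference line."""

    ttp_current: float  # months, after re-irradiation
    ttp_reference: float  # months, after the prior (or first) line of therapy

    def __post_init__(self) -> None:
        if self.ttp_current <= 0 or self.ttp_reference <= 0:
            raise TrialStatsError("times to progression must be positive")

    @property
    def ratio(self) -> float:
        return self.ttp_current / self.ttp_reference


@dataclass(frozen=True)
class TTPComparison:
    mean_trial: float
    mean_control: float
    t_statistic: float
    p_value: float
    n_trial: int
    n_control: int
    log_scale: bool


def ttp_ratio_test(
    trial: Sequence[TTPRecord],
    control: Sequence[TTPRecord],
    log_scale: bool = False,
) -> TTPComparison:
    """Welch two-sample t-test comparing per-patient TTP ratios between arms.

    The test runs on raw ratios by default; ``log_scale`` switches to log
    ratios for users preferring a symmetric scale.
    """
    if len(trial) < 2 or len(control) < 2:
        raise TrialStatsError("each group needs at least two records")
    a = np.array([r.ratio for r in trial])
    b = np.array([r.ratio for r in control])
    if log_scale:
        a, b = np.log(a), np.log(b)
    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return TTPComparison(
        mean_trial=float(a.mean()),
        mean_control=float(b.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_trial=len(a),
        n_control=len(b),
        log_scale=log_scale,
    )


def impute_median(values: Sequence[Optional[float]]) -> list[float]:
    """Replace missing entries (None or NaN) by the cohort median.

    The median of an even number of observed values is the midpoint of the
    two central values; observed entries pass through unchanged.
    """
    observed = [
        v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    if not observed:
        raise TrialStatsError("cannot impute: all values missing")
    med = float(np.median(observed))
    return [
        med if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        for v in values
    ]


def covariate_table(
    df: pd.DataFrame,
    n_col: str = "n_fractions",
    dose_col: str = "dose_per_fraction",
    kps_col: Optional[str] = "kps",
    alpha_beta: float = _bed.ALPHA_BETA_TUMOR,
) -> pd.DataFrame:
    """Analysis-ready covariate table for downstream regression models.

    Adds the tumor BED covariate (alpha/beta = 10 Gy by default) computed
    from per-course fractionation columns, and median-imputes the Karnofsky
    performance status column if present.
    """
    out = df.copy()
    out["bed"] = [
        _bed.bed_single(int(n), float(d), alpha_beta)
        for n, d in zip(out[n_col], out[dose_col])
    ]
    if kps_col is not None and kps_col in out.columns:
        out[kps_col] = impute_median(out[kps_col].tolist())
    return out
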