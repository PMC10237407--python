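"""Mouse-to-human survival-benefit translation by linear regression.

Interventions with a measured survival benefit in a murine glioma model and
a known hazard ratio (HR) in patients define a regression of log hazard
ratio on the mouse benefit metric; a new intervention's mouse benefit then
yields a predicted patient HR with a t-based prediction interval.  The log
link keeps predicted hazard ratios positive for any input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


class TranslationError(ValueError):
    """Degenerate or insufficient data for the translation regression."""


@dataclass(frozen=True)
class BenefitRecord:
    """One intervention: benefit in the mouse model and observed human HR."""

    intervention_id: str
    mouse_benefit: float  # e.g. ratio of median survivals, treated/control
    human_hr: float

    def __post_init__(self) -> None:
        if self.mouse_benefit <= 0:
            raise TranslationError("mouse benefit must be positive")
        if self.human_hr <= 0:
            raise TranslationError("hazard ratio must be positive")


@dataclass(frozen=True)
class TranslationFit:
    """OLS fit of ln(HR) on the mouse benefit metric."""

    intercept: float
    slope: float
    residual_sd: float  # n-2 denominator; 0.0 when n == 2 (exact fit)
    n_obs: int
    x_mean: float
    sxx: float  # sum of squared centered x

    @property
    def has_uncertainty(self) -> bool:
        return self.n_obs >= 3


def fit_translation(records: Sequence[BenefitRecord]) -> TranslationFit:
    """Ordinary least squares of ln(human HR) on mouse benefit.

    Closed-form normal equations; requires >= 2 records with distinct
    benefit values.
    """
    if len(records) < 2:
        raise TranslationError("at least two records required")
    x = np.array([r.mouse_benefit for r in records], dtype=float)
    y = np.log([r.human_hr for r in records])
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise TranslationError("all mouse benefits identical; slope not identifiable")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    n = len(records)
    resid = y - (intercept + slope * x)
    residual_sd = math.sqrt(float(np.sum(resid**2)) / (n - 2)) if n > 2 else 0.0
    return TranslationFit(
        intercept=intercept,
        slope=slope,
        residual_sd=residual_sd,
        n_obs=n,
        x_mean=float(x.mean()),
        sxx=sxx,
    )


@dataclass(frozen=True)
class HRPrediction:
    """Predicted hazard ratio with a prediction interval."""

    hr: float
    lower: float
    upper: float
    level: float


def predict_hr(
    fit: TranslationFit, mouse_benefit: float, level: float = 0.95
) -> HRPrediction:
    """Predicted patient HR for a given mouse benefit.

    The interval is the t-based prediction interval for a new observation
    on the log-HR scale, exponentiated.  With only two training points the
    residual variance is zero and the interval collapses to the point.
    """
    log_hr = fit.intercept + fit.slope * mouse_benefit
    hr = math.exp(log_hr)
    if not fit.has_uncertainty or fit.residual_sd == 0.0:
        return HRPrediction(hr=hr, lower=hr, upper=hr, level=level)
    se_pred = fit.residual_sd * math.sqrt(
        1.0 + 1.0 / fit.n_obs + (mouse_benefit - fit.x_mean) ** 2 / fit.sxx
    )
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, fit.n_obs - 2))
    return HRPrediction(
        hr=hr,
        lower=math.exp(log_hr - tcrit * se_pred),
        upper=math.exp(log_hr + tcrit * se_pred),
        level=level,
    )
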