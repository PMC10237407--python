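"""Seeded synthetic-data generators for every pipeline input.

The trial's patient-level data and the supplementary mouse-to-human
regression dataset are not public, so these generators produce stand-ins
with the statistical structure the analyses assume: jittered adherence logs
around a prescribed calendar, right-censored exponential survival cohorts
with a specified median, benefit/HR pairs scattered around a known
regression line, and log-normal perturbations of the plasticity parameters
for robustness sweeps.  Every generator is a pure function of its arguments
and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .plasticity import DEFAULT_PARAMS, PlasticityParams, SimulationError
from .schedule import Schedule, per_day_counts
from .translation import BenefitRecord
from .trial import AdherenceRecord, SurvivalRecord


class GenerationError(RuntimeError):
    """A generator could not satisfy its output invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of generation settings used by the end-to-end pipeline demo."""

    seed: int = 0
    n_patients: int = 14
    n_control: int = 92
    tid_jitter_sd: float = 0.25  # h
    qd_jitter_sd: float = 2.0  # h
    missing_rate: float = 0.0
    pfs_median_months: float = 4.4
    os_median_months: float = 7.3
    censor_frac: float = 0.2
    translation_intercept: float = 0.2
    translation_slope: float = -0.5
    translation_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("missing_rate", "censor_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name} must lie in [0, 1], got {v}")


def gen_adherence_logs(
    schedule: Schedule,
    n_patients: int,
    tid_jitter_sd: float = 0.25,
    qd_jitter_sd: float = 2.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> list[list[AdherenceRecord]]:
    """Adherence logs with truncated-normal jitter around the planned times.

    Jitter is normal with the given per-kind standard deviation, truncated
    at +/- 3 sd; fractions are independently missing with ``missing_rate``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise GenerationError("missing rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fractions = schedule.expand()
    counts = per_day_counts(fractions)
    kinds = ["TID" if counts[f.day_index] > 1 else "QD" for f in fractions]
    sds = np.array([tid_jitter_sd if k == "TID" else qd_jitter_sd for k in kinds])
    planned = np.array([f.abs_time_h for f in fractions])

    logs: list[list[AdherenceRecord]] = []
    for _ in range(n_patients):
        jitter = rng.normal(0.0, 1.0, size=len(planned))
        jitter = np.clip(jitter, -3.0, 3.0) * sds
        missing = rng.uniform(size=len(planned)) < missing_rate
        log = [
            AdherenceRecord(
                planned_h=float(p),
                actual_h=None if m else float(p + j),
                phase_kind=k,
            )
            for p, j, m, k in zip(planned, jitter, missing, kinds)
        ]
        logs.append(log)
    return logs


def gen_survival_cohort(
    n: int,
    median_months: float,
    censor_frac: float = 0.0,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """Right-censored exponential survival cohort.

    Event times are exponential with rate ln(2)/median.  Censoring is by an
    independent exponential clock whose rate is chosen so a fraction
    ``censor_frac`` of subjects is censored in expectation; an observation
    is censored when its censoring time precedes its event time.
    """
    if median_months <= 0:
        raise GenerationError("median must be positive")
    if not 0.0 <= censor_frac < 1.0:
        raise GenerationError("censoring fraction must lie in [0, 1)")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    rate = np.log(2.0) / median_months
    t_event = rng.exponential(1.0 / rate, size=n)
    if censor_frac == 0.0:
        return [SurvivalRecord(time=float(t), event=True) for t in t_event]
    # with two competing exponentials, P(censor first) = rc / (rc + rate)
    rc = rate * censor_frac / (1.0 - censor_frac)
    t_cens = rng.exponential(1.0 / rc, size=n)
    return [
        SurvivalRecord(time=float(min(te, tc)), event=bool(te <= tc))
        for te, tc in zip(t_event, t_cens)
    ]


def gen_translation_records(
    n: int,
    intercept: float = 0.2,
    slope: float = -0.5,
    noise_sd: float = 0.05,
    x_range: tuple[float, float] = (0.5, 2.5),
    seed: int = 0,
) -> list[BenefitRecord]:
    """Benefit/HR pairs on a known log-linear line with Gaussian noise."""
    if n < 2:
        raise GenerationError("at least two records required for a fit")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*x_range, size=n)
    log_hr = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    return [
        BenefitRecord(
            intervention_id=f"intervention_{i:03d}",
            mouse_benefit=float(xi),
            human_hr=float(np.exp(lh)),
        )
        for i, (xi, lh) in enumerate(zip(x, log_hr))
    ]


_POSITIVE_FIELDS = (
    "rho_S",
    "rho_D",
    "mu",
    "alpha_S",
    "beta_S",
    "alpha_D",
    "beta_D",
    "nu_max",
    "t_peak",
    "log_width",
    "tau_S",
    "tau_D",
)


def gen_param_perturbations(
    base: PlasticityParams = DEFAULT_PARAMS,
    rel_sd: float = 0.1,
    n: int = 10,
    seed: int = 0,
    max_attempts: int = 1000,
) -> list[PlasticityParams]:
    """Log-normal multiplicative perturbations of the model parameters.

    Each field is multiplied by an independent log-normal factor with log-sd
    ``rel_sd``; draws violating the parameter invariants (stem resistance,
    quiescence and growth-rate orderings, nu_max <= 1) are rejected and
    redrawn, up to ``max_attempts`` per sample.
    """
    if rel_sd < 0:
        raise GenerationError("relative sd must be non-negative")
    if rel_sd == 0:
        return [base] * n
    rng = np.random.default_rng(seed)
    out: list[PlasticityParams] = []
    base_dict = asdict(base)
    for _ in range(n):
        for _attempt in range(max_attempts):
            factors = rng.lognormal(0.0, rel_sd, size=len(_POSITIVE_FIELDS))
            cand = dict(base_dict)
            for name, f in zip(_POSITIVE_FIELDS, factors):
                cand[name] = base_dict[name] * float(f)
            cand["nu_max"] = min(cand["nu_max"], 1.0)
            try:
                out.append(PlasticityParams(**cand))
                break
            except SimulationError:
                continue
        else:
            raise GenerationError(
                f"could not satisfy parameter invariants in {max_attempts} attempts"
            )
    return out
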