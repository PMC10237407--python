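"""Exhaustive evaluation of isotoxic candidate schedules and sensitivity sweeps.

The admissible design space under the clinical constraints (<= 2 phases,
<= 10 weekdays, <= 3 fractions/day at 1.0 Gy, BED matched to 35 Gy / 10 fx
at alpha/beta = 2 Gy) contains on the order of a hundred designs, so the
search is exhaustive: every candidate is simulated with the plasticity
model and ranked by the model-predicted time to progression.  Four
sensitivity analyses are provided: the TID interfraction interval, the
start day of the work week, the clock time of day, and random jitter of the
administration times within the clinically tolerated windows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from . import bed as _bed
from .plasticity import (
    DEFAULT_PARAMS,
    PlasticityParams,
    TumorState,
    default_initial_state,
    simulate,
    time_to_progression,
)
from .schedule import (
    STANDARD_CONSTRAINTS,
    ConstraintSet,
    Schedule,
    enumerate_candidates,
)


class OptimizerError(ValueError):
    """Invalid optimizer configuration."""


@dataclass(frozen=True)
class SimSettings:
    """Shared simulation settings for schedule evaluation."""

    horizon: float = 24.0 * 730.0  # hours (2 years)
    sample_step: float = 6.0  # hours
    initial_total: float = 1e6
    initial_stem_fraction: float = 0.05
    alpha_beta: float = _bed.ALPHA_BETA_CNS

    def initial_state(self) -> TumorState:
        return default_initial_state(self.initial_total, self.initial_stem_fraction)


DEFAULT_SIM = SimSettings()


@dataclass(frozen=True)
class EvaluationResult:
    """Simulation-derived metrics for one candidate schedule."""

    schedule: Schedule
    metric: float  # time to progression, hours (horizon if censored)
    censored: bool
    end_volume: float  # relative to initial volume
    end_stem_fraction: float
    total_bed: float  # Gy at the evaluation alpha/beta

    def metric_days(self) -> float:
        return self.metric / 24.0


def evaluate(
    schedule: Schedule,
    params: PlasticityParams = DEFAULT_PARAMS,
    sim: SimSettings = DEFAULT_SIM,
) -> EvaluationResult:
    """Deterministically simulate one schedule and extract its metrics."""
    traj = simulate(
        schedule,
        params=params,
        initial=sim.initial_state(),
        horizon=sim.horizon,
        sample_step=sim.sample_step,
    )
    ttp = time_to_progression(traj)
    end_idx = int(np.searchsorted(traj.times, traj.treatment_end, side="right")) - 1
    end_volume = float(traj.volume[end_idx]) / sim.initial_total
    end_stem = float(traj.stem_fraction[end_idx])
    return EvaluationResult(
        schedule=schedule,
        metric=float(ttp.time_h) if not ttp.censored else sim.horizon,
        censored=ttp.censored,
        end_volume=end_volume,
        end_stem_fraction=end_stem,
        total_bed=schedule.total_bed(sim.alpha_beta),
    )


def _n_tid_fractions(schedule: Schedule) -> int:
    return sum(p.n_fractions for p in schedule.phases if p.fractions_per_day > 1)


def _design_key(schedule: Schedule) -> tuple:
    return tuple(
        (p.n_fractions, p.fractions_per_day, round(p.dose_per_fraction, 9))
        for p in schedule.phases
    )


def optimize(
    constraints: ConstraintSet = STANDARD_CONSTRAINTS,
    params: PlasticityParams = DEFAULT_PARAMS,
    tid_interval: float = 3.25,
    reference_bed: Optional[float] = None,
    sim: SimSettings = DEFAULT_SIM,
) -> list[EvaluationResult]:
    """Evaluate every admissible candidate and rank by predicted benefit.

    Sorting is by time to progression descending; ties break by smaller
    end-of-treatment volume, then fewer TID fractions (patient convenience),
    then lexicographic design.
    """
    candidates = enumerate_candidates(
        constraints,
        tid_interval=tid_interval,
        reference_bed=reference_bed,
        alpha_beta=sim.alpha_beta,
    )
    if not candidates:
        raise OptimizerError("empty candidate set under the given constraints")
    results = [evaluate(s, params, sim) for s in candidates]
    results.sort(
        key=lambda r: (
            -r.metric,
            r.end_volume,
            _n_tid_fractions(r.schedule),
            _design_key(r.schedule),
        )
    )
    return results


def sweep_interval(
    schedule: Schedule,
    params: PlasticityParams = DEFAULT_PARAMS,
    grid: Sequence[float] = (),
    sim: SimSettings = DEFAULT_SIM,
) -> list[tuple[float, Optional[float]]]:
    """Metric as a function of the TID interfraction interval.

    The multi-fraction phases are re-timed at each grid value; intervals
    that are non-positive or push a day's last fraction past midnight yield
    a ``None`` metric (invalid marker).
    """
    if not any(p.fractions_per_day > 1 for p in schedule.phases):
        raise OptimizerError("interval sweep requires a multi-fraction phase")
    out: list[tuple[float, Optional[float]]] = []
    for dt in grid:
        if dt <= 0:
            out.append((dt, None))
            continue
        cand = schedule.with_tid_interval(dt)
        try:
            res = evaluate(cand, params, sim)
        except Exception:
            out.append((dt, None))
            continue
        out.append((dt, res.metric))
    return out


def sweep_start_day(
    schedule: Schedule,
    params: PlasticityParams = DEFAULT_PARAMS,
    sim: SimSettings = DEFAULT_SIM,
) -> list[tuple[int, float]]:
    """Metric for each possible weekday start (Monday..Friday)."""
    out = []
    for wd in range(5):
        cand = replace(schedule, start_weekday=wd)
        out.append((wd, evaluate(cand, params, sim).metric))
    return out


def sweep_time_of_day(
    schedule: Schedule,
    params: PlasticityParams = DEFAULT_PARAMS,
    times: Sequence[float] = (8.0, 9.0, 10.0, 11.0),
    sim: SimSettings = DEFAULT_SIM,
) -> list[tuple[float, Optional[float]]]:
    """Metric for each daily start clock time.

    The model carries no circadian term and the simulation clock starts at
    the first fraction, so valid entries are identical; a start time that
    pushes a multi-fraction day past midnight is marked invalid (``None``).
    """
    out: list[tuple[float, Optional[float]]] = []
    for t in times:
        cand = replace(schedule, daily_time=t)
        try:
            res = evaluate(cand, params, sim)
        except Exception:
            out.append((t, None))
            continue
        out.append((t, res.metric))
    return out


@dataclass(frozen=True)
class JitterSummary:
    """Distribution of the metric under administration-time jitter."""

    nominal: float
    mean: float
    minimum: float
    maximum: float
    q05: float
    q25: float
    median: float
    q75: float
    q95: float
    n_rep: int


def adherence_jitter(
    schedule: Schedule,
    params: PlasticityParams = DEFAULT_PARAMS,
    tid_window: float = 1.0,
    qd_window: float = 24.0,
    n_rep: int = 200,
    seed: int = 0,
    sim: SimSettings = DEFAULT_SIM,
) -> JitterSummary:
    """Monte Carlo sensitivity of the metric to administration-time jitter.

    Each replicate perturbs every fraction time independently and uniformly
    within its tolerance window (TID fractions +/- ``tid_window`` h, QD
    fractions +/- ``qd_window`` h), truncating so the course stays strictly
    ordered, then re-simulates.
    """
    if tid_window < 0 or qd_window < 0:
        raise OptimizerError("jitter windows must be non-negative")
    if n_rep < 1:
        raise OptimizerError("at least one replicate required")
    fractions = schedule.expand()
    from .schedule import per_day_counts

    counts = per_day_counts(fractions)
    times = np.array([f.abs_time_h for f in fractions])
    doses = np.array([f.dose for f in fractions])
    windows = np.array(
        [tid_window if counts[f.day_index] > 1 else qd_window for f in fractions]
    )

    nominal = _metric_from_times(times, doses, params, sim)
    rng = np.random.default_rng(seed)
    metrics = np.empty(n_rep)
    for r in range(n_rep):
        jit = rng.uniform(-windows, windows)
        t = times + jit
        # enforce strict ordering by truncating backward drift
        for i in range(1, len(t)):
            if t[i] <= t[i - 1]:
                t[i] = t[i - 1] + 1e-6
        metrics[r] = _metric_from_times(t, doses, params, sim)
    q05, q25, q50, q75, q95 = np.quantile(metrics, [0.05, 0.25, 0.5, 0.75, 0.95])
    return JitterSummary(
        nominal=nominal,
        mean=float(metrics.mean()),
        minimum=float(metrics.min()),
        maximum=float(metrics.max()),
        q05=float(q05),
        q25=float(q25),
        median=float(q50),
        q75=float(q75),
        q95=float(q95),
        n_rep=n_rep,
    )


def _metric_from_times(
    times: np.ndarray,
    doses: np.ndarray,
    params: PlasticityParams,
    sim: SimSettings,
) -> float:
    traj = simulate(
        list(zip(times, doses)),
        params=params,
        initial=sim.initial_state(),
        horizon=sim.horizon,
        sample_step=sim.sample_step,
    )
    ttp = time_to_progression(traj)
    return float(ttp.time_h) if not ttp.censored else sim.horizon
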