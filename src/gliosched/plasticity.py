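"""Two-compartment stem-like / differentiated tumor dynamics under radiation.

The tumor is modeled as a treatment-resistant, slowly proliferating
stem-like population S and a treatment-sensitive, faster differentiated
population D coupled by differentiation (S -> D at rate ``mu``) and by
radiation-induced dedifferentiation (D -> S at each fraction).  Between
fractions the populations follow the linear system

    dS/dt = (rho_S - mu) * S
    dD/dt = mu * S + rho_D * D

integrated in exact piecewise closed form; after each fraction a compartment
is growth-arrested (quiescent) for ``tau_S`` / ``tau_D`` hours, with stem
cells quiescing longer than differentiated cells.  At a fraction of dose d
delivered ``delta_t`` hours after the previous one, each compartment is
killed by its own linear-quadratic surviving fraction and a fraction
``nu(delta_t)`` of the surviving differentiated cells dedifferentiates:

    S' = S * SF_S(d) + nu(delta_t) * D * SF_D(d)
    D' = (1 - nu(delta_t)) * D * SF_D(d)

``nu`` is a log-normal-shaped window of the interfraction interval, maximal
at ``t_peak`` (3.25 h) and floored to zero for the first fraction of a
course and for intervals of a day or more.  Tumor volume is proportional to
S + D; "time to progression" is the first post-treatment time at which the
volume re-attains its pre-treatment baseline.

Trajectory sample times are non-decreasing rather than strictly increasing:
each fraction instant is recorded twice, once with the pre-kill and once
with the post-kill populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .schedule import Fraction, Schedule

#: Interval at or beyond which radiation-induced dedifferentiation is nil.
DEDIFF_CUTOFF_H = 24.0


class SimulationError(ValueError):
    """Invalid state or arguments for a simulation."""


@dataclass(frozen=True)
class PlasticityParams:
    """Model parameters (rates per hour, LQ coefficients per Gy / Gy^2).

    The defaults are a calibration: only ``t_peak`` = 3.25 h and the
    qualitative orderings (stem cells more radioresistant, slower cycling,
    longer quiescent than differentiated cells) are biologically anchored;
    the remaining magnitudes were chosen so that the simulated isotoxic
    course comparisons reproduce the expected qualitative ranking (see
    docs/methods.md).
    """

    rho_S: float = math.log(2.0) / (21.0 * 24.0) / 4.0  # stem net growth, /h
    rho_D: float = math.log(2.0) / (21.0 * 24.0)  # differentiated growth, /h
    mu: float = 1e-5  # differentiation S -> D, /h
    alpha_S: float = 0.025  # /Gy
    beta_S: float = 0.0025  # /Gy^2
    alpha_D: float = 0.1  # /Gy
    beta_D: float = 0.01  # /Gy^2
    nu_max: float = 0.55  # peak dedifferentiation fraction
    t_peak: float = 3.25  # h, interval of maximal dedifferentiation
    log_width: float = 0.6  # dimensionless window shape
    tau_S: float = 96.0  # h, stem quiescence after a fraction
    tau_D: float = 24.0  # h, differentiated quiescence after a fraction

    def __post_init__(self) -> None:
        if min(self.rho_S, self.rho_D, self.mu) < 0:
            raise SimulationError("rates must be non-negative")
        if not (self.alpha_S < self.alpha_D and self.beta_S <= self.beta_D):
            raise SimulationError(
                "stem cells must be more radioresistant (alpha_S < alpha_D, beta_S <= beta_D)"
            )
        if not self.tau_S > self.tau_D:
            raise SimulationError("stem quiescence must exceed differentiated quiescence")
        if self.rho_S > self.rho_D:
            raise SimulationError("stem cells must not outgrow differentiated cells")
        if not 0.0 <= self.nu_max <= 1.0:
            raise SimulationError("nu_max must lie in [0, 1]")
        if self.t_peak <= 0 or self.log_width <= 0:
            raise SimulationError("t_peak and log_width must be positive")


DEFAULT_PARAMS = PlasticityParams()


@dataclass(frozen=True)
class TumorState:
    """Cell counts and per-compartment quiescence clocks (absolute hours)."""

    S: float
    D: float
    quiescent_until_S: float = -math.inf
    quiescent_until_D: float = -math.inf

    def __post_init__(self) -> None:
        if self.S < 0 or self.D < 0:
            raise SimulationError(f"negative population (S={self.S}, D={self.D})")

    @property
    def total(self) -> float:
        return self.S + self.D

    @property
    def stem_fraction(self) -> float:
        tot = self.total
        return self.S / tot if tot > 0 else 0.0


def default_initial_state(total: float = 1e6, stem_fraction: float = 0.05) -> TumorState:
    """Pre-treatment tumor: mostly differentiated cells, 5% stem-like."""
    return TumorState(S=total * stem_fraction, D=total * (1.0 - stem_fraction))


@dataclass
class Trajectory:
    """Sampled time course of the simulation.

    ``times`` is non-decreasing; each fraction instant appears twice
    (pre-kill then post-kill).  Times are hours since the first fraction.
    """

    times: np.ndarray
    S: np.ndarray
    D: np.ndarray
    treatment_end: float = 0.0  # time of the last fraction

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if not (len(self.times) == len(self.S) == len(self.D)):
            raise SimulationError("trajectory arrays must have equal length")

    @property
    def volume(self) -> np.ndarray:
        """Relative tumor volume (proportional to total cell count)."""
        return self.S + self.D

    @property
    def stem_fraction(self) -> np.ndarray:
        tot = self.volume
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, self.S / np.maximum(tot, 1e-300), 0.0)
        return frac


@dataclass(frozen=True)
class ProgressionTime:
    """Time to progression in hours, or censored at the horizon."""

    time_h: Optional[float]
    censored: bool

    @property
    def observed(self) -> bool:
        return not self.censored


def lq_survival(dose: float, alpha: float, beta: float) -> float:
    """Linear-quadratic surviving fraction exp(-alpha*d - beta*d^2)."""
    if dose < 0:
        raise SimulationError(f"negative dose {dose}")
    return math.exp(-alpha * dose - beta * dose * dose)


def dediff_fraction(delta_t: Optional[float], params: PlasticityParams = DEFAULT_PARAMS) -> float:
    """Dedifferentiation fraction nu(delta_t) for an interfraction interval.

    Log-normal-shaped window with its single interior maximum exactly at
    ``t_peak``; zero for the first fraction of a course (``delta_t`` None)
    and for intervals of 24 h or more.
    """
    if delta_t is None:
        return 0.0
    if delta_t <= 0:
        raise SimulationError(f"interfraction interval must be positive, got {delta_t}")
    if delta_t >= DEDIFF_CUTOFF_H:
        return 0.0
    z = math.log(delta_t / params.t_peak) / params.log_width
    return params.nu_max * math.exp(-0.5 * z * z)


def apply_fraction(
    state: TumorState,
    dose: float,
    delta_t: Optional[float],
    t_now: float,
    params: PlasticityParams = DEFAULT_PARAMS,
) -> TumorState:
    """Instantaneous effect of one fraction: LQ kill plus dedifferentiation."""
    if dose < 0:
        raise SimulationError(f"negative dose {dose}")
    if dose == 0:
        return state
    sf_s = lq_survival(dose, params.alpha_S, params.beta_S)
    sf_d = lq_survival(dose, params.alpha_D, params.beta_D)
    nu = dediff_fraction(delta_t, params)
    s_new = state.S * sf_s + nu * state.D * sf_d
    d_new = (1.0 - nu) * state.D * sf_d
    return TumorState(
        S=s_new,
        D=d_new,
        quiescent_until_S=t_now + params.tau_S,
        quiescent_until_D=t_now + params.tau_D,
    )


def _segment_evolve(
    s0: float,
    d0: float,
    dt: float,
    s_active: bool,
    d_active: bool,
    params: PlasticityParams,
) -> tuple[float, float]:
    """Closed-form solution of the linear system over one homogeneous segment.

    A quiescent compartment has its growth rate and (for S) its
    differentiation outflow set to zero.
    """
    rho_s = params.rho_S if s_active else 0.0
    mu = params.mu if s_active else 0.0
    rho_d = params.rho_D if d_active else 0.0
    a = rho_s - mu
    s1 = s0 * math.exp(a * dt)
    if mu == 0.0:
        d1 = d0 * math.exp(rho_d * dt)
    elif abs(a - rho_d) > 1e-15:
        d1 = d0 * math.exp(rho_d * dt) + mu * s0 * (
            (math.exp(a * dt) - math.exp(rho_d * dt)) / (a - rho_d)
        )
    else:
        d1 = math.exp(rho_d * dt) * (d0 + mu * s0 * dt)
    return s1, d1


def _segments(state: TumorState, t_from: float, t_to: float) -> list[tuple[float, float, bool, bool]]:
    """Split [t_from, t_to] at quiescence-clock expiries.

    Returns (seg_start, seg_end, s_active, d_active) tuples.
    """
    cuts = sorted(
        {t_from, t_to}
        | {
            t
            for t in (state.quiescent_until_S, state.quiescent_until_D)
            if t_from < t < t_to
        }
    )
    out = []
    for a, b in zip(cuts, cuts[1:]):
        s_active = a >= state.quiescent_until_S
        d_active = a >= state.quiescent_until_D
        out.append((a, b, s_active, d_active))
    return out


def grow(
    state: TumorState,
    t_from: float,
    t_to: float,
    params: PlasticityParams = DEFAULT_PARAMS,
) -> TumorState:
    """Evolve the state from ``t_from`` to ``t_to`` with no radiation."""
    if t_to < t_from:
        raise SimulationError(f"t_to {t_to} precedes t_from {t_from}")
    s, d = state.S, state.D
    for a, b, s_act, d_act in _segments(state, t_from, t_to):
        s, d = _segment_evolve(s, d, b - a, s_act, d_act, params)
    return replace(state, S=s, D=d)


def _sample_growth(
    state: TumorState,
    t_from: float,
    t_to: float,
    params: PlasticityParams,
    sample_times: np.ndarray,
) -> tuple[TumorState, list[tuple[float, float, float]]]:
    """Evolve and record the state at each requested time in (t_from, t_to]."""
    samples: list[tuple[float, float, float]] = []
    s, d = state.S, state.D
    for a, b, s_act, d_act in _segments(state, t_from, t_to):
        inside = sample_times[(sample_times > a) & (sample_times <= b)]
        for t in inside:
            ss, dd = _segment_evolve(s, d, float(t) - a, s_act, d_act, params)
            samples.append((float(t), ss, dd))
        s, d = _segment_evolve(s, d, b - a, s_act, d_act, params)
    return replace(state, S=s, D=d), samples


ScheduleLike = Union[Schedule, Sequence[Fraction]]


def _fraction_times_doses(schedule: ScheduleLike) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(schedule, Schedule):
        fractions = schedule.expand()
        times = np.array([f.abs_time_h for f in fractions])
        doses = np.array([f.dose for f in fractions])
    else:
        fractions = list(schedule)
        if fractions and isinstance(fractions[0], Fraction):
            times = np.array([f.abs_time_h for f in fractions])
            doses = np.array([f.dose for f in fractions])
        else:  # (time, dose) pairs
            arr = np.asarray(fractions, dtype=float)
            times, doses = (arr[:, 0], arr[:, 1]) if arr.size else (np.array([]), np.array([]))
    if len(times):
        order = np.argsort(times, kind="stable")
        times, doses = times[order], doses[order]
        times = times - times[0]  # clock origin: first fraction instant
    return times, doses


def simulate(
    schedule: ScheduleLike,
    params: PlasticityParams = DEFAULT_PARAMS,
    initial: Optional[TumorState] = None,
    horizon: float = 24.0 * 730.0,
    sample_step: float = 6.0,
) -> Trajectory:
    """Simulate a course of radiation and the subsequent regrowth.

    Time 0 is the first fraction instant (or the start of observation for an
    empty schedule), so the model is exactly invariant to the clock time of
    day at which treatment is delivered.  The trajectory is sampled every
    ``sample_step`` hours plus at every fraction instant, where the pre- and
    post-kill populations are both recorded.
    """
    if initial is None:
        initial = default_initial_state()
    if sample_step <= 0:
        raise SimulationError("sample step must be positive")
    times, doses = _fraction_times_doses(schedule)
    if len(times) and times[-1] > horizon:
        raise SimulationError(
            f"last fraction at {times[-1]:.1f} h lies beyond the horizon {horizon:.1f} h"
        )

    grid = np.arange(0.0, horizon + 0.5 * sample_step, sample_step)
    grid = grid[grid <= horizon]

    rec_t: list[float] = [0.0]
    rec_s: list[float] = [initial.S]
    rec_d: list[float] = [initial.D]

    state = initial
    t = 0.0
    prev_fx_time: Optional[float] = None
    for fx_time, dose in zip(times, doses):
        if fx_time > t:
            # grid points landing exactly on the fraction instant are covered
            # by the explicit pre-kill record below
            state, samples = _sample_growth(state, t, fx_time, params, grid[grid < fx_time])
            for st, ss, dd in samples:
                rec_t.append(st), rec_s.append(ss), rec_d.append(dd)
            t = fx_time
        # pre-kill record (skip duplicate of the t=0 initial record)
        if fx_time > 0.0 or prev_fx_time is not None:
            rec_t.append(fx_time), rec_s.append(state.S), rec_d.append(state.D)
        delta_t = None if prev_fx_time is None else fx_time - prev_fx_time
        state = apply_fraction(state, float(dose), delta_t, fx_time, params)
        rec_t.append(fx_time), rec_s.append(state.S), rec_d.append(state.D)
        prev_fx_time = fx_time
        t = fx_time
    if horizon > t:
        state, samples = _sample_growth(state, t, horizon, params, grid)
        for st, ss, dd in samples:
            rec_t.append(st), rec_s.append(ss), rec_d.append(dd)

    return Trajectory(
        times=np.array(rec_t),
        S=np.array(rec_s),
        D=np.array(rec_d),
        treatment_end=float(times[-1]) if len(times) else 0.0,
    )


def time_to_progression(
    traj: Trajectory, baseline_volume: Optional[float] = None
) -> ProgressionTime:
    """First post-treatment time at which the volume re-attains baseline.

    Baseline defaults to the initial volume.  An untreated (never shrinking)
    trajectory progresses immediately at the treatment end; a trajectory
    that stays below baseline for the whole horizon is censored.  The
    crossing is located by linear interpolation between samples.
    """
    if baseline_volume is None:
        baseline_volume = float(traj.volume[0])
    t = traj.times
    v = traj.volume
    mask = t >= traj.treatment_end
    if not mask.any():
        raise SimulationError("trajectory does not cover the treatment period")
    idx = np.nonzero(mask)[0]
    tt, vv = t[idx], v[idx]
    above = vv >= baseline_volume
    if above[0]:
        return ProgressionTime(time_h=float(tt[0]), censored=False)
    cross = np.nonzero(above)[0]
    if len(cross) == 0:
        return ProgressionTime(time_h=None, censored=True)
    i = cross[0]
    t0, t1 = tt[i - 1], tt[i]
    v0, v1 = vv[i - 1], vv[i]
    if v1 == v0 or t1 == t0:
        return ProgressionTime(time_h=float(t1), censored=False)
    frac = (baseline_volume - v0) / (v1 - v0)
    return ProgressionTime(time_h=float(t0 + frac * (t1 - t0)), censored=False)
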