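import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliosched.plasticity import (
    DEFAULT_PARAMS,
    SimulationError,
    TumorState,
    apply_fraction,
    dediff_fraction,
    default_initial_state,
    grow,
    lq_survival,
    simulate,
    time_to_progression,
)


class TestLQSurvival:
    def test_zero_dose_identity(self):
        assert lq_survival(0.0, 0.3, 0.03) == 1.0

    def test_hand_value(self):
        # alpha*d + beta*d^2 = 0.6 + 0.12 = 0.72
        assert lq_survival(2.0, 0.3, 0.03) == pytest.approx(math.exp(-0.72))

    def test_negative_dose_rejected(self):
        with pytest.raises(SimulationError):
            lq_survival(-1.0, 0.3, 0.03)

    @pytest.mark.parametrize("dose", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_stem_cells_more_radioresistant(self, dose, params):
        assert lq_survival(dose, params.alpha_S, params.beta_S) > lq_survival(
            dose, params.alpha_D, params.beta_D
        )


class TestDediffWindow:
    def test_peak_interval_attains_maximum(self, params):
        assert dediff_fraction(3.25, params) == pytest.approx(params.nu_max)

    def test_first_fraction_has_no_dedifferentiation(self, params):
        assert dediff_fraction(None, params) == 0.0

    def test_long_intervals_floored(self, params):
        assert dediff_fraction(24.0, params) == 0.0
        assert dediff_fraction(72.0, params) == 0.0

    def test_grid_argmax_at_peak(self, params):
        grid = np.arange(0.25, 12.01, 0.25)
        values = [dediff_fraction(dt, params) for dt in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(3.25)

    @settings(derandomize=True, max_examples=50)
    @given(
        t_peak=st.floats(0.5, 10.0),
        log_width=st.floats(0.1, 2.0),
        nu_max=st.floats(0.01, 1.0),
    )
    def test_argmax_equals_t_peak_for_any_params(self, t_peak, log_width, nu_max):
        p = dataclasses.replace(
            DEFAULT_PARAMS, t_peak=t_peak, log_width=log_width, nu_max=nu_max
        )
        # the window is unimodal in log(dt); compare the peak against offsets
        at_peak = dediff_fraction(t_peak, p)
        assert at_peak == pytest.approx(nu_max)
        for factor in (0.5, 0.9, 1.1, 2.0):
            dt = t_peak * factor
            if dt < 24.0:
                assert dediff_fraction(dt, p) < at_peak


class TestApplyFraction:
    def test_zero_dose_leaves_state_unchanged(self, params):
        state = TumorState(1e4, 1e5)
        assert apply_fraction(state, 0.0, None, 0.0, params) is state

    def test_pure_lq_kill_without_dedifferentiation(self, params):
        state = TumorState(1e4, 1e5)
        out = apply_fraction(state, 2.0, None, 0.0, params)  # first fraction: nu = 0
        assert out.S == pytest.approx(1e4 * lq_survival(2.0, params.alpha_S, params.beta_S))
        assert out.D == pytest.approx(1e5 * lq_survival(2.0, params.alpha_D, params.beta_D))

    def test_survivor_conservation_at_peak_interval(self, params):
        """With no stem cells, dedifferentiation re-partitions the D survivors."""
        state = TumorState(0.0, 1e6)
        out = apply_fraction(state, 1.0, 3.25, 10.0, params)
        sf_d = lq_survival(1.0, params.alpha_D, params.beta_D)
        assert out.S == pytest.approx(params.nu_max * 1e6 * sf_d)
        assert out.D == pytest.approx((1.0 - params.nu_max) * 1e6 * sf_d)
        assert out.S + out.D == pytest.approx(1e6 * sf_d)

    def test_quiescence_clocks_set(self, params):
        out = apply_fraction(TumorState(1e4, 1e5), 1.0, None, 100.0, params)
        assert out.quiescent_until_S == 100.0 + params.tau_S
        assert out.quiescent_until_D == 100.0 + params.tau_D

    @settings(derandomize=True, max_examples=100)
    @given(
        s=st.floats(0.0, 1e7),
        d=st.floats(0.0, 1e7),
        dose=st.floats(0.0, 10.0),
        delta_t=st.one_of(st.none(), st.floats(0.5, 30.0)),
    )
    def test_never_creates_cells(self, s, d, dose, delta_t):
        state = TumorState(s, d)
        out = apply_fraction(state, dose, delta_t, 0.0, DEFAULT_PARAMS)
        assert out.S >= 0.0 and out.D >= 0.0
        assert out.S + out.D <= s + d + 1e-9 * (s + d)


def stepper_oracle(state, t_from, t_to, params, dt=5e-3):
    """Brute-force fixed-step (midpoint) integration of the growth system.

    The step divides the quiescence expiry times used in the test so no step
    straddles an activity switch.
    """

    def rates(t, s, d):
        s_active = t >= state.quiescent_until_S
        d_active = t >= state.quiescent_until_D
        rho_s = params.rho_S if s_active else 0.0
        mu = params.mu if s_active else 0.0
        rho_d = params.rho_D if d_active else 0.0
        return (rho_s - mu) * s, mu * s + rho_d * d

    s, d = state.S, state.D
    t = t_from
    while t < t_to - 1e-12:
        h = min(dt, t_to - t)
        ds1, dd1 = rates(t, s, d)
        ds2, dd2 = rates(t + 0.5 * h, s + 0.5 * h * ds1, d + 0.5 * h * dd1)
        s, d = s + h * ds2, d + h * dd2
        t += h
    return s, d


class TestGrowth:
    def test_exponential_closed_form_without_coupling(self):
        p = dataclasses.replace(DEFAULT_PARAMS, mu=0.0)
        state = TumorState(1e4, 1e5)
        out = grow(state, 0.0, 100.0, p)
        assert out.S == pytest.approx(1e4 * math.exp(p.rho_S * 100.0), rel=1e-12)
        assert out.D == pytest.approx(1e5 * math.exp(p.rho_D * 100.0), rel=1e-12)

    def test_fully_quiescent_interval_is_static(self, params):
        state = TumorState(1e4, 1e5, quiescent_until_S=200.0, quiescent_until_D=200.0)
        out = grow(state, 0.0, 150.0, params)
        assert out.S == 1e4 and out.D == 1e5

    def test_backwards_time_rejected(self, params):
        with pytest.raises(SimulationError):
            grow(TumorState(1.0, 1.0), 10.0, 5.0, params)

    def test_coupled_system_matches_euler_oracle(self):
        """Closed-form piecewise solution vs. fine-step Euler, with quiescence."""
        p = dataclasses.replace(DEFAULT_PARAMS, mu=5e-4)  # strengthen coupling
        state = TumorState(5e4, 2e5, quiescent_until_S=30.0, quiescent_until_D=10.0)
        out = grow(state, 0.0, 50.0, p)
        s_ref, d_ref = stepper_oracle(state, 0.0, 50.0, p)
        assert out.S == pytest.approx(s_ref, rel=1e-6)
        assert out.D == pytest.approx(d_ref, rel=1e-6)


class TestSimulate:
    def test_untreated_course_matches_closed_form(self, params):
        """Zero-treatment limit: trajectory equals the linear-ODE solution."""
        initial = default_initial_state()
        traj = simulate([], params, initial=initial, horizon=2000.0, sample_step=50.0)
        for t, s, d in zip(traj.times, traj.S, traj.D):
            ref = grow(initial, 0.0, float(t), params)
            assert s == pytest.approx(ref.S, rel=1e-9)
            assert d == pytest.approx(ref.D, rel=1e-9)

    def test_ablative_fraction_collapses_population(self, params):
        traj = simulate(
            [(0.0, 100.0)], params, horizon=200.0, sample_step=10.0
        )
        post = traj.volume[traj.times > 0.0]
        assert post.max() < 1.0  # essentially sterilized within the window

    def test_trial_course_enriches_stem_fraction(self, trial, params):
        traj = simulate(trial, params)
        end_idx = np.searchsorted(traj.times, traj.treatment_end, side="right") - 1
        assert traj.stem_fraction[end_idx] > traj.stem_fraction[0]

    def test_records_pre_and_post_kill(self, trial, params):
        traj = simulate(trial, params)
        # at an interior fraction instant the time appears twice with a drop
        t16 = trial.expand()
        t_second = t16[1].abs_time_h - t16[0].abs_time_h
        idx = np.nonzero(np.isclose(traj.times, t_second))[0]
        assert len(idx) == 2
        assert traj.volume[idx[1]] < traj.volume[idx[0]]

    def test_dose_scaling_never_increases_end_burden(self, trial, params):
        """Uniformly scaling all doses up cannot leave more cells at course end."""
        fx = trial.expand()
        base = [(f.abs_time_h, f.dose) for f in fx]
        up = [(t, 1.5 * d) for t, d in base]
        end = fx[-1].abs_time_h - fx[0].abs_time_h
        v_base = simulate(base, params, horizon=end + 24, sample_step=6.0)
        v_up = simulate(up, params, horizon=end + 24, sample_step=6.0)
        assert v_up.volume[-1] <= v_base.volume[-1]


class TestTimeToProgression:
    def test_untreated_progresses_immediately(self, params):
        traj = simulate([], params, horizon=1000.0, sample_step=50.0)
        ttp = time_to_progression(traj)
        assert not ttp.censored and ttp.time_h == 0.0

    def test_interpolated_crossing_matches_dense_sampling(self, trial, params):
        coarse = simulate(trial, params, sample_step=24.0)
        dense = simulate(trial, params, sample_step=0.5)
        t_coarse = time_to_progression(coarse).time_h
        t_dense = time_to_progression(dense).time_h
        assert t_coarse == pytest.approx(t_dense, rel=2e-3)

    def test_censored_when_horizon_too_short(self, trial, params):
        fx = trial.expand()
        end = fx[-1].abs_time_h - fx[0].abs_time_h
        traj = simulate(trial, params, horizon=end + 48.0, sample_step=6.0)
        assert time_to_progression(traj).censored


class TestParameterInvariants:
    @pytest.mark.parametrize(
        "override",
        [
            {"alpha_S": 0.2},  # not more resistant than differentiated
            {"tau_S": 10.0},  # shorter quiescence than differentiated
            {"rho_S": 0.01},  # faster cycling than differentiated
            {"nu_max": 1.5},
            {"t_peak": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, override):
        with pytest.raises(SimulationError):
            dataclasses.replace(DEFAULT_PARAMS, **override)

    def test_negative_population_rejected(self):
        with pytest.raises(SimulationError):
            TumorState(-1.0, 1.0)
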