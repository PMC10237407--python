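import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliosched.synth import gen_survival_cohort
from gliosched.trial import (
    AdherenceRecord,
    SurvivalRecord,
    TTPRecord,
    TrialStatsError,
    assess_adherence,
    covariate_table,
    exact_binomial_upper,
    impute_median,
    km_estimate,
    ttp_ratio_test,
)


def cp_upper_oracle(failures, n, confidence=0.95, tol=1e-10):
    """Bisection on the binomial CDF: smallest p with P(X <= f | n, p) <= 1 - conf."""
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if stats.binom.cdf(failures, n, mid) <= 1.0 - confidence:
            hi = mid
        else:
            lo = mid
    return hi


class TestExactBinomialUpper:
    def test_feasibility_threshold_met_with_zero_failures(self):
        """0 non-adherent of 14 gives an upper bound below the 20% bar."""
        assert exact_binomial_upper(0, 14) == pytest.approx(0.19264, abs=5e-6)
        assert exact_binomial_upper(0, 14) <= 0.20

    @pytest.mark.parametrize(
        "failures, n, pct",
        [(1, 14, 30), (5, 27, 35)],
    )
    def test_reported_bounds(self, failures, n, pct):
        assert round(100 * exact_binomial_upper(failures, n)) == pct

    def test_all_failures_bound_is_one(self):
        assert exact_binomial_upper(14, 14) == 1.0

    def test_monotone_in_failures(self):
        bounds = [exact_binomial_upper(f, 20) for f in range(21)]
        assert all(b > a for a, b in zip(bounds, bounds[1:]))

    @pytest.mark.parametrize("failures, n", [(0, 14), (1, 14), (5, 27), (3, 8), (19, 20)])
    def test_matches_binomial_cdf_inversion(self, failures, n):
        assert exact_binomial_upper(failures, n) == pytest.approx(
            cp_upper_oracle(failures, n), abs=1e-8
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(TrialStatsError):
            exact_binomial_upper(-1, 10)
        with pytest.raises(TrialStatsError):
            exact_binomial_upper(11, 10)
        with pytest.raises(TrialStatsError):
            exact_binomial_upper(0, 0)
        with pytest.raises(TrialStatsError):
            exact_binomial_upper(0, 10, confidence=1.0)


class TestAdherence:
    def test_on_time_course_completed(self):
        log = [
            AdherenceRecord(0.0, 0.1, "QD"),
            AdherenceRecord(24.0, 23.5, "QD"),
            AdherenceRecord(48.0, 48.5, "TID"),
        ]
        res = assess_adherence(log)
        assert res.completed and res.n_compliant == 3

    def test_tid_window_is_one_hour(self):
        ok = assess_adherence([AdherenceRecord(10.0, 11.0, "TID")])
        late = assess_adherence([AdherenceRecord(10.0, 11.0 + 1 / 60, "TID")])
        assert ok.completed and not late.completed

    def test_qd_window_is_24_hours(self):
        ok = assess_adherence([AdherenceRecord(10.0, 33.0, "QD")])
        late = assess_adherence([AdherenceRecord(10.0, 35.0, "QD")])
        assert ok.completed and not late.completed

    def test_missing_fraction_blocks_completion(self):
        res = assess_adherence(
            [AdherenceRecord(0.0, 0.0, "QD"), AdherenceRecord(24.0, None, "QD")]
        )
        assert not res.completed
        assert res.fractions[1].missing and res.fractions[1].deviation_h is None

    def test_record_order_irrelevant(self):
        a = [AdherenceRecord(0.0, 0.5, "QD"), AdherenceRecord(24.0, 23.0, "QD")]
        assert assess_adherence(a) == assess_adherence(a[::-1])

    def test_duplicate_planned_times_rejected(self):
        with pytest.raises(TrialStatsError):
            assess_adherence([AdherenceRecord(5.0, 5.0, "QD"), AdherenceRecord(5.0, 5.1, "QD")])
        with pytest.raises(TrialStatsError):
            assess_adherence([])


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = km_estimate([SurvivalRecord(t, True) for t in times])
        for k, t in enumerate(times):
            assert res.survival_at(t) == pytest.approx(1.0 - (k + 1) / 5)
        assert res.median == pytest.approx(3.0)

    def test_all_censored_median_not_reached(self):
        res = km_estimate([SurvivalRecord(t, False) for t in (1.0, 2.0, 3.0)])
        assert not res.median_reached and res.median is None
        assert res.survival_at(3.0) == pytest.approx(1.0)

    def test_survival_before_first_event_is_one(self):
        res = km_estimate([SurvivalRecord(2.0, True)])
        assert res.survival_at(1.0) == 1.0

    def test_recovers_exponential_median_under_censoring(self):
        cohort = gen_survival_cohort(2000, median_months=4.4, censor_frac=0.2, seed=0)
        res = km_estimate(cohort)
        assert res.median_reached
        assert res.median == pytest.approx(4.4, rel=0.05)


class TestTTPRatioTest:
    def test_identical_groups_not_significant(self):
        grp = [TTPRecord(6.0, 4.0), TTPRecord(5.0, 5.0), TTPRecord(8.0, 4.0)]
        res = ttp_ratio_test(grp, grp)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_detects_prolonged_ttp(self):
        """Power > 90% for ratio means 1.5 vs 1.0 (sd 0.3, n = 50 + 50)."""
        rejections = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            trial = [
                TTPRecord(float(max(r, 0.05) * 4.0), 4.0)
                for r in rng.normal(1.5, 0.3, size=50)
            ]
            control = [
                TTPRecord(float(max(r, 0.05) * 4.0), 4.0)
                for r in rng.normal(1.0, 0.3, size=50)
            ]
            rejections += ttp_ratio_test(trial, control).p_value < 0.05
        assert rejections / 200 > 0.9

    def test_log_scale_option(self):
        trial = [TTPRecord(8.0, 4.0), TTPRecord(9.0, 3.0)]
        control = [TTPRecord(4.0, 4.0), TTPRecord(3.0, 3.0)]
        res = ttp_ratio_test(trial, control, log_scale=True)
        assert res.log_scale
        assert res.mean_trial == pytest.approx(np.mean([np.log(2.0), np.log(3.0)]))

    def test_small_groups_rejected(self):
        with pytest.raises(TrialStatsError):
            ttp_ratio_test([TTPRecord(1.0, 1.0)], [TTPRecord(1.0, 1.0), TTPRecord(2.0, 1.0)])


class TestImputation:
    def test_examples(self):
        assert impute_median([1.0, None, 3.0]) == [1.0, 2.0, 3.0]
        assert impute_median([70.0, 80.0, None, 90.0, 100.0]) == [
            70.0,
            80.0,
            85.0,
            90.0,
            100.0,
        ]

    def test_nan_treated_as_missing(self):
        out = impute_median([1.0, float("nan"), 5.0])
        assert out == [1.0, 3.0, 5.0]

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(42)
        values = list(rng.normal(size=11))
        with_missing = values[:5] + [None] + values[5:]
        out = impute_median(with_missing)
        s = sorted(values)
        oracle = (s[5] + s[5]) / 2 if len(s) % 2 else (s[4] + s[5]) / 2
        assert out[5] == pytest.approx(oracle)

    def test_all_missing_rejected(self):
        with pytest.raises(TrialStatsError):
            impute_median([None, None])


class TestCovariateTable:
    def test_bed_column_uses_tumor_alpha_beta(self):
        df = pd.DataFrame(
            {"n_fractions": [10, 16], "dose_per_fraction": [3.5, 1.0], "kps": [80.0, None]}
        )
        out = covariate_table(df)
        assert out["bed"].iloc[0] == pytest.approx(47.25)
        assert out["bed"].iloc[1] == pytest.approx(16 * 1.0 * 1.1)
        assert out["kps"].iloc[1] == 80.0  # single observed value imputed

    def test_input_frame_untouched(self):
        df = pd.DataFrame({"n_fractions": [10], "dose_per_fraction": [3.5]})
        covariate_table(df, kps_col=None)
        assert "bed" not in df.columns
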