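"""Survival-statistics kernels against independent oracles and lifelines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from progmod import adjust_pvalues, hazard_ratio, km_curve, logrank

from _oracles import bh_oracle, cox_hr_grid_oracle, km_oracle, logrank_oracle


def _random_arm(rng, n):
    t = rng.exponential(10, n).round(1) + 0.1
    e = (rng.random(n) > 0.3).astype(int)
    return t, e


class TestLogrank:
    def test_matches_risk_table_oracle_on_random_fixtures(self, rng):
        for _ in range(25):
            ta, ea = _random_arm(rng, int(rng.integers(4, 15)))
            tb, eb = _random_arm(rng, int(rng.integers(4, 15)))
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank(ta, ea, tb, eb)
            chi2, p = logrank_oracle(ta, ea, tb, eb)
            assert res.statistic == pytest.approx(chi2, rel=1e-9, abs=1e-12)
            assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        for _ in range(10):
            ta, ea = _random_arm(rng, 20)
            tb, eb = _random_arm(rng, 25)
            res = logrank(ta, ea, tb, eb)
            ll = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-6)
            assert res.p_value == pytest.approx(ll.p_value, rel=1e-6)

    def test_identical_groups_give_null_result(self):
        t = np.array([2.0, 5.0, 7.0, 9.0])
        e = np.array([1, 0, 1, 1])
        res = logrank(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_label_symmetry(self, surv_pair):
        ta, ea, tb, eb = surv_pair(seed=3)
        r1 = logrank(ta, ea, tb, eb)
        r2 = logrank(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.observed == r2.observed[::-1]

    def test_invariant_under_monotone_time_transform(self, surv_pair):
        ta, ea, tb, eb = surv_pair(seed=4)
        r1 = logrank(ta, ea, tb, eb)
        f = lambda t: np.log1p(t) ** 3
        r2 = logrank(f(ta), ea, f(tb), eb)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_zero_events_flagged_degenerate(self):
        t = np.array([1.0, 2.0, 3.0])
        z = np.zeros(3, dtype=int)
        res = logrank(t, z, t + 1, z)
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [], [1.0, 2.0], [1, 1])

    def test_null_type_one_error_calibrated(self):
        """Under a shared exponential law the 5% rejection rate should be
        hit within 2 Monte-Carlo SEs."""
        r = np.random.default_rng(42)
        n_sim, n = 2000, 30
        rej = 0
        for _ in range(n_sim):
            t = r.exponential(5, 2 * n)
            e = (r.random(2 * n) > 0.25).astype(int)
            res = logrank(t[:n], e[:n], t[n:], e[n:])
            rej += res.p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) < 2 * se + 1e-12


class TestHazardRatio:
    def test_matches_partial_likelihood_grid_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(6):
            ta, ea = _random_arm(rng, 8)
            tb, eb = _random_arm(rng, 8)
            if ea.sum() == 0 or eb.sum() == 0:
                continue
            hr = hazard_ratio(ta, ea, tb, eb)
            if not 1e-3 < hr < 1e3:  # MLE unbounded under separation
                continue
            oracle = cox_hr_grid_oracle(ta, ea, tb, eb)
            assert hr == pytest.approx(oracle, rel=2e-3)

    def test_matches_lifelines_cox(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        ta, ea = _random_arm(rng, 40)
        tb, eb = _random_arm(rng, 35)
        hr = hazard_ratio(ta, ea, tb, eb)
        df = pd.DataFrame({
            "t": np.concatenate([ta, tb]),
            "e": np.concatenate([ea, eb]),
            "x": np.r_[np.ones(40), np.zeros(35)],
        })
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert hr == pytest.approx(float(np.exp(cph.params_["x"])), rel=1e-4)

    def test_identical_groups_give_unity(self):
        t = np.array([1.0, 3.0, 5.0, 8.0, 9.0])
        e = np.array([1, 1, 0, 1, 0])
        assert hazard_ratio(t, e, t, e) == pytest.approx(1.0, abs=1e-5)

    def test_swapping_groups_inverts(self, surv_pair):
        ta, ea, tb, eb = surv_pair(seed=9)
        h1 = hazard_ratio(ta, ea, tb, eb)
        h2 = hazard_ratio(tb, eb, ta, ea)
        assert h1 == pytest.approx(1.0 / h2, rel=1e-4)

    def test_zero_events_reported_missing(self):
        t = np.array([1.0, 2.0, 3.0])
        assert np.isnan(hazard_ratio(t, [0, 0, 0], t, [1, 1, 1]))

    def test_pike_estimator_from_risk_table(self, surv_pair):
        ta, ea, tb, eb = surv_pair(seed=5)
        res = logrank(ta, ea, tb, eb)
        expected = (res.observed[0] / res.expected[0]) / (
            res.observed[1] / res.expected[1])
        assert hazard_ratio(ta, ea, tb, eb, method="pike") == pytest.approx(expected)

    def test_recovers_true_hr_two(self):
        """Proportional-hazards data with true HR=2: mean estimate within
        15% at n=200/group over a fixed seed set."""
        hrs = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            ta = r.exponential(1 / 2.0, 200)  # hazard 2
            tb = r.exponential(1.0, 200)      # hazard 1
            c = r.exponential(2.0, 400)
            t = np.minimum(np.concatenate([ta, tb]), c)
            e = (np.concatenate([ta, tb]) <= c).astype(int)
            hrs.append(hazard_ratio(t[:200], e[:200], t[200:], e[200:]))
        assert abs(np.mean(hrs) - 2.0) / 2.0 < 0.15


class TestKaplanMeier:
    def test_matches_hand_product_limit_on_interleaved_censoring(self):
        t = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        km = km_curve(t, e)
        oracle = km_oracle(t, e)
        assert list(km.event_times) == sorted(oracle)
        for tau, s in zip(km.event_times, km.survival_prob):
            assert s == pytest.approx(oracle[tau], rel=1e-12)

    def test_matches_random_oracles(self, rng):
        for _ in range(10):
            t, e = _random_arm(rng, int(rng.integers(5, 25)))
            km = km_curve(t, e)
            oracle = km_oracle(t, e)
            for tau, s in zip(km.event_times, km.survival_prob):
                assert s == pytest.approx(oracle[tau], rel=1e-12)

    def test_all_censored_curve_stays_at_one(self):
        km = km_curve([3.0, 6.0, 9.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at([0.0, 5.0, 100.0]) == pytest.approx([1, 1, 1])

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(4, 40)
        km = km_curve(t, np.ones(40, dtype=int))
        for tau, s in zip(km.event_times, km.survival_prob):
            assert s == pytest.approx((t > tau).mean(), abs=1e-12)

    def test_single_subject_event_drops_to_zero(self):
        km = km_curve([4.2], [1])
        assert km.survival_at(4.2) == pytest.approx(0.0)
        assert km.survival_at(4.1) == pytest.approx(1.0)

    def test_censored_at_event_time_remains_at_risk(self):
        # at t=2: 3 at risk (incl. the censored one), 1 death -> S=2/3
        km = km_curve([2.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_prob[0] == pytest.approx(2 / 3)


class TestAdjustPvalues:
    def test_bh_matches_step_up_formula(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert adjust_pvalues(p) == pytest.approx(bh_oracle(p))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_bh_matches_oracle_property(self, p):
        assert adjust_pvalues(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_all_equal_stay_equal_and_single_unchanged(self):
        out = adjust_pvalues([0.2, 0.2, 0.2])
        assert np.allclose(out, out[0])
        assert adjust_pvalues([0.37]) == pytest.approx([0.37])

    def test_bonferroni_and_bad_input(self):
        assert adjust_pvalues([0.01, 0.4], "bonferroni") == pytest.approx([0.02, 0.8])
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])
        with pytest.raises(ValueError):
            adjust_pvalues([0.1], method="holm-bogus")

    def test_nan_passthrough(self):
        out = adjust_pvalues([0.01, np.nan, 0.02])
        assert np.isnan(out[1]) and not np.isnan(out[0])
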