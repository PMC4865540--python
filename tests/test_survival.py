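"""Kaplan-Meier, log-rank, tertiles, Cox, ROC/Youden, Pearson."""

import numpy as np
import pytest

import petdlbcl as p


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        curve = p.km_estimate([5.0] * 10, [False] * 10)
        assert curve.at(5.0) == 1.0
        assert curve.at(0.0) == 1.0

    def test_hand_product_limit_example(self):
        # event at 1 (risk set 3), censored at 2, event at 3 (risk set 1)
        curve = p.km_estimate([1.0, 2.0, 3.0], [True, False, True])
        assert curve.at(1.0) == pytest.approx(2.0 / 3.0)
        assert curve.at(2.5) == pytest.approx(2.0 / 3.0)
        assert curve.at(3.0) == pytest.approx(0.0)

    def test_large_exponential_sample_matches_closed_form(self):
        rng = np.random.default_rng(42)
        h = 0.3
        t = rng.exponential(1.0 / h, size=5000)
        curve = p.km_estimate(t, np.ones(5000, bool))
        for tt in (0.5, 1.0, 2.0, 4.0):
            assert curve.at(tt) == pytest.approx(np.exp(-h * tt), abs=0.02)

    def test_uncensored_km_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0.1, 5.0, size=200)
        curve = p.km_estimate(t, np.ones(200, bool))
        for tt in (0.5, 1.5, 3.0):
            assert curve.at(tt) == pytest.approx((t > tt).mean())

    def test_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        curve = p.km_estimate(rng.exponential(2, 300), rng.random(300) < 0.6)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival.min() >= 0 and curve.survival.max() <= 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            p.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_near_zero(self):
        t = np.arange(1, 51, dtype=float)
        e = np.tile([True, False], 25)
        chi2, pval = p.logrank([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert pval > 0.99

    def test_label_order_invariance(self):
        rng = np.random.default_rng(7)
        g1 = (rng.exponential(2, 80), rng.random(80) < 0.7)
        g2 = (rng.exponential(1, 80), rng.random(80) < 0.7)
        assert p.logrank([g1, g2])[0] == pytest.approx(p.logrank([g2, g1])[0])

    def test_power_under_hazard_ratio_three(self):
        """HR 3 with 500/arm is detected in >= 95 % of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t1 = rng.exponential(1.0, 500)
            t2 = rng.exponential(1.0 / 3.0, 500)
            e = np.ones(500, bool)
            _, pval = p.logrank([(t1, e), (t2, e)])
            hits += pval < 0.05
        assert hits >= 19

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            p.logrank([(np.array([1.0]), np.array([True])), (np.array([]), np.array([]))])


class TestTertiles:
    def test_one_to_nine_splits_in_threes(self):
        groups = p.tertile_groups(np.arange(1, 10))
        np.testing.assert_array_equal(groups, [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_all_equal_values_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            groups = p.tertile_groups(np.full(9, 4.0))
        assert set(groups) == {1}

    def test_matches_sort_and_split_oracle(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=300)
        groups = p.tertile_groups(v)
        q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
        oracle = np.array([1 if x <= q1 else 2 if x <= q2 else 3 for x in v])
        np.testing.assert_array_equal(groups, oracle)

    def test_ties_go_to_the_lower_group(self):
        groups = p.tertile_groups([1, 1, 1, 1, 2, 2, 3, 3, 3])
        assert groups[3] == 1  # the tied boundary value stays low


class TestCoxFit:
    def test_identical_groups_hr_one(self):
        t = np.arange(1, 41, dtype=float)
        e = np.tile([True, False], 20)
        fit = p.cox_fit(np.concatenate([t, t]), np.concatenate([e, e]),
                        np.array([0] * 40 + [1] * 40))
        hr, lo, hi = fit.hazard_ratios[1]
        assert hr == pytest.approx(1.0, abs=0.05)
        assert lo < 1.0 < hi

    def test_recovers_true_hazard_ratio_two(self):
        rng = np.random.default_rng(5)
        n = 1000
        t = np.concatenate([rng.exponential(1.0, n), rng.exponential(0.5, n)])
        e = np.ones(2 * n, bool)
        fit = p.cox_fit(t, e, np.array([0] * n + [1] * n))
        hr, lo, hi = fit.hazard_ratios[1]
        log_se = (np.log(hi) - np.log(lo)) / (2 * 1.96)
        assert abs(np.log(hr) - np.log(2.0)) < 3 * log_se

    def test_trend_larger_for_ordered_than_shuffled_groups(self):
        rng = np.random.default_rng(6)
        scales = [1.0, 0.5, 0.25]
        t = np.concatenate([rng.exponential(s, 150) for s in scales])
        e = np.ones(450, bool)
        g = np.repeat([0, 1, 2], 150)
        ordered = p.cox_fit(t, e, g).trend_chi2
        shuffled = []
        for seed in range(5):
            perm = np.random.default_rng(seed).permutation(g)
            shuffled.append(p.cox_fit(t, e, perm).trend_chi2)
        assert ordered > max(shuffled)

    def test_trend_score_test_agrees_with_likelihood_ratio(self):
        """The hand-written score test tracks lifelines' LR statistic."""
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(8)
        t = np.concatenate([rng.exponential(s, 200) for s in (1.0, 0.7, 0.4)])
        e = np.ones(600, bool)
        g = np.repeat([0.0, 1.0, 2.0], 200)
        chi2, _ = p.logrank_trend(t, e, g)
        cph = CoxPHFitter().fit(pd.DataFrame({"T": t, "E": 1, "g": g}), "T", "E")
        lr = cph.log_likelihood_ratio_test().test_statistic
        assert chi2 == pytest.approx(lr, rel=0.10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            p.cox_fit([1.0, 2.0], [False, False], [0, 1])

    def test_level_without_events_flagged(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(1, 60)
        e = np.array([True] * 30 + [False] * 30)
        fit = p.cox_fit(t, e, np.array([0] * 30 + [1] * 30))
        assert any("no events" in d for d in fit.diagnostics)

    def test_hr_invariant_to_time_unit(self):
        rng = np.random.default_rng(10)
        t = np.concatenate([rng.exponential(1.0, 300), rng.exponential(0.5, 300)])
        e = np.ones(600, bool)
        g = np.array([0] * 300 + [1] * 300)
        hr_years = p.cox_fit(t, e, g).hazard_ratios[1][0]
        hr_days = p.cox_fit(t * 365.25, e, g).hazard_ratios[1][0]
        assert hr_years == pytest.approx(hr_days, rel=1e-6)


class TestRoc:
    def test_perfect_separation(self):
        v = np.array([1, 2, 3, 10, 11, 12], float)
        y = np.array([0, 0, 0, 1, 1, 1], bool)
        res = p.roc_optimal_cutoff(v, y)
        assert res.youden == pytest.approx(1.0)
        assert res.sensitivity_at_optimum == 1.0
        assert res.specificity_at_optimum == 1.0
        assert 3 < res.optimal_cutoff <= 10

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(12)
        v = rng.normal(size=150)
        y = rng.random(150) < 1 / (1 + np.exp(-2 * v))
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        res = p.roc_optimal_cutoff(v, y)
        best = -np.inf
        for c in np.concatenate([np.unique(v) - 1e-9, np.unique(v) + 1e-9]):
            sens = (v[y] >= c).mean()
            spec = (v[~y] < c).mean()
            best = max(best, sens + spec - 1)
        assert res.youden == pytest.approx(best, abs=1e-12)

    def test_flip_outcomes_with_reversed_direction_keeps_youden(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=100)
        y = rng.random(100) < 1 / (1 + np.exp(-3 * v))
        res = p.roc_optimal_cutoff(v, y)
        flipped = p.roc_optimal_cutoff(-v, ~y)
        assert flipped.youden == pytest.approx(res.youden)

    def test_agrees_with_sklearn_youden(self):
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(14)
        v = rng.normal(size=200)
        y = rng.random(200) < 1 / (1 + np.exp(-2 * v))
        res = p.roc_optimal_cutoff(v, y)
        fpr, tpr, _ = roc_curve(y, v)
        assert res.youden == pytest.approx((tpr - fpr).max(), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            p.roc_optimal_cutoff([1.0, 2.0, 3.0], [True, True, True])


class TestPearson:
    def test_linear_relations(self):
        x = np.arange(10, dtype=float)
        assert p.pearson_r(x, 2 * x) == pytest.approx(1.0)
        assert p.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(size=(2, 80))
        r = p.pearson_r(x, y)
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            p.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_cox_regression_table_shape(cohort_2000):
    _, df = cohort_2000
    work = df.copy()
    work["mtv0_tertile"] = p.tertile_groups(work["mtv0"].to_numpy())
    table = p.cox_regression_table(
        work, "time_years", "event",
        factors={"MTV-0 tertile": "mtv0_tertile", "DS": "ds"},
        multivariate=["MTV-0 tertile", "DS"],
    )
    assert set(table["factor"]) == {"MTV-0 tertile", "DS"}
    assert {"HR_uva", "HR_mva", "trend_chi2_uva", "trend_chi2_mva"} <= set(table.columns)
    ref = table[(table["factor"] == "MTV-0 tertile") & (table["level"] == 1)]
    assert ref["HR_uva"].iloc[0] == 1.0
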