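"""Validity measures, CIs, AUC, McNemar, Bland-Altman, regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from abpscreen.stats import (
    ConfusionTable,
    auc_empirical,
    auc_point,
    bland_altman,
    confusion_table,
    difference_regression,
    likelihood_ratios,
    mcnemar_test,
    pearson_correlation,
    proportion_ci,
    validity_metrics,
)


def brute_force_auc(scores, labels):
    """Exhaustive positive-negative pair counting, ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exact_mcnemar_by_summation(b, c):
    """Two-sided binomial tail: sum pmf over outcomes no more likely than b."""
    n = b + c
    p_obs = binom.pmf(b, n, 0.5)
    return min(1.0, sum(
        binom.pmf(k, n, 0.5) for k in range(n + 1)
        if binom.pmf(k, n, 0.5) <= p_obs * (1 + 1e-9)
    ))


class TestConfusionTable:
    def test_all_four_cells(self):
        t = confusion_table([True, True, False, False], [True, False, True, False])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 1)

    def test_all_positive(self):
        t = confusion_table([True] * 5, [True] * 5)
        assert (t.tp, t.fp, t.fn, t.tn) == (5, 0, 0, 0)

    def test_twelve_subject_fixture_hand_count(self):
        screen = [1, 1, 1, 0, 0, 0, 1, 0, 1, 1, 0, 0]
        ref = [1, 0, 1, 1, 0, 0, 1, 1, 0, 1, 0, 1]
        t = confusion_table([bool(x) for x in screen], [bool(x) for x in ref])
        assert (t.tp, t.fp, t.fn, t.tn) == (4, 2, 3, 3)
        assert t.total == 12

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion_table([True], [True, False])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ConfusionTable(-1, 0, 0, 0)

    def test_cellwise_addition(self):
        a = ConfusionTable(1, 2, 3, 4)
        b = ConfusionTable(5, 6, 7, 8)
        assert a + b == ConfusionTable(6, 8, 10, 12)


class TestProportionCI:
    def test_wilson_reconstructs_printed_interval(self):
        # 232 of 347 -> 67% (62, 72) after integer rounding
        est = proportion_ci(232, 347, "wilson")
        assert round(est.estimate * 100) == 67
        assert round(est.ci_low * 100) == 62
        assert round(est.ci_high * 100) == 72

    def test_exact_zero_successes_lower_bound_zero(self):
        est = proportion_ci(0, 10, "exact")
        assert est.estimate == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high > 0.0

    def test_exact_all_successes_upper_bound_one(self):
        est = proportion_ci(10, 10, "exact")
        assert est.ci_high == 1.0

    @pytest.mark.parametrize("method", ["wilson", "exact", "wald"])
    def test_interval_brackets_estimate(self, method):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(1, 400))
            k = int(rng.integers(0, n + 1))
            est = proportion_ci(k, n, method)
            assert est.ci_low <= est.estimate <= est.ci_high
            assert 0.0 <= est.ci_low and est.ci_high <= 1.0

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 3)
        with pytest.raises(ValueError, match="method"):
            proportion_ci(1, 2, "magic")


class TestValidityMetrics:
    def test_symmetric_table(self):
        m = validity_metrics(ConfusionTable(1, 1, 1, 1))
        assert all(m[k].estimate == 0.5 for k in ("sensitivity", "specificity", "ppv", "npv"))

    def test_perfect_table(self):
        m = validity_metrics(ConfusionTable(10, 0, 0, 15))
        assert all(m[k].estimate == 1.0 for k in m)

    def test_reconstructed_sensitivity(self):
        m = validity_metrics(ConfusionTable(232, 0, 115, 0))
        assert m["sensitivity"].estimate * 100 == pytest.approx(66.86, abs=0.01)

    def test_zero_denominator_flagged_undefined(self):
        m = validity_metrics(ConfusionTable(0, 0, 0, 4))
        assert not m["sensitivity"].defined
        assert not m["ppv"].defined
        assert m["specificity"].estimate == 1.0

    def test_sensitivity_times_denominator_is_tp(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            t = ConfusionTable(*(int(x) for x in rng.integers(1, 200, 4)))
            m = validity_metrics(t)
            assert m["sensitivity"].estimate * (t.tp + t.fn) == pytest.approx(t.tp)


class TestLikelihoodRatios:
    def test_uninformative(self):
        lr = likelihood_ratios(ConfusionTable(1, 1, 1, 1))
        assert lr["lr_pos"].estimate == pytest.approx(1.0)
        assert lr["lr_neg"].estimate == pytest.approx(1.0)

    def test_arithmetic(self):
        # sens 0.8 (80/100), spec 0.9 (90/100)
        lr = likelihood_ratios(ConfusionTable(80, 10, 20, 90))
        assert lr["lr_pos"].estimate == pytest.approx(8.0)
        assert lr["lr_neg"].estimate == pytest.approx(2.0 / 9.0)
        assert lr["lr_pos"].ci_low < 8.0 < lr["lr_pos"].ci_high

    def test_perfect_test_infinite_lr(self):
        lr = likelihood_ratios(ConfusionTable(10, 0, 0, 10))
        assert math.isinf(lr["lr_pos"].estimate)
        assert lr["lr_neg"].estimate == 0.0


class TestAUC:
    def test_chance_point(self):
        assert auc_point(ConfusionTable(1, 1, 1, 1)) == 0.5

    def test_perfect_point(self):
        assert auc_point(ConfusionTable(5, 0, 0, 5)) == 1.0

    def test_point_arithmetic(self):
        # sens 0.67 (67/100), spec 0.76 (76/100)
        assert auc_point(ConfusionTable(67, 24, 33, 76)) == pytest.approx(0.715)

    def test_empirical_perfect_separation(self):
        est = auc_empirical([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert est.estimate == 1.0

    def test_empirical_six_point_toy_equals_brute_force(self):
        scores = [3.0, 1.0, 2.0, 2.0, 5.0, 4.0]
        labels = [True, False, True, False, True, False]
        est = auc_empirical(scores, labels)
        assert est.estimate == pytest.approx(brute_force_auc(scores, labels))

    def test_empirical_random_instances_equal_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            scores = rng.integers(0, 6, n).astype(float)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            est = auc_empirical(scores, labels)
            assert est.estimate == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_empirical_null_near_half(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.4
        est = auc_empirical(scores, labels)
        assert est.estimate == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_empirical([1, 2], [True, True])


class TestMcNemar:
    def test_symmetric_counts(self):
        res = mcnemar_test(7, 7, mode="asymptotic")
        assert res["statistic"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_exact_equals_direct_summation(self):
        res = mcnemar_test(10, 2, mode="exact")
        assert res["p_value"] == pytest.approx(exact_mcnemar_by_summation(10, 2))

    @pytest.mark.parametrize("b,c", [(0, 5), (3, 3), (8, 1), (12, 12), (1, 11)])
    def test_exact_oracle_grid(self, b, c):
        res = mcnemar_test(b, c, mode="exact")
        assert res["p_value"] == pytest.approx(exact_mcnemar_by_summation(b, c))

    def test_asymptotic_statistic(self):
        res = mcnemar_test(20, 5, mode="asymptotic")
        assert res["statistic"] == pytest.approx(9.0)

    def test_auto_mode_switch(self):
        assert mcnemar_test(5, 5)["mode"] == "exact"
        assert mcnemar_test(20, 10)["mode"] == "asymptotic"

    def test_degenerate(self):
        res = mcnemar_test(0, 0)
        assert res["mode"] == "degenerate"
        assert res["p_value"] == 1.0


class TestBlandAltman:
    def test_identity_pairs(self):
        x = np.array([100.0, 120.0, 140.0, 160.0])
        res = bland_altman(x, x)
        assert res.mean_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert math.isnan(res.pitman_r)

    def test_loa_formula(self):
        rng = np.random.default_rng(12)
        x = rng.normal(130, 15, 200)
        y = x - rng.normal(5, 8, 200)
        res = bland_altman(x, y)
        assert res.loa_low == pytest.approx(res.mean_diff - 1.96 * res.sd_diff, abs=1e-6)
        assert res.loa_high == pytest.approx(res.mean_diff + 1.96 * res.sd_diff, abs=1e-6)
        assert abs(res.pitman_r) <= 1.0

    def test_equal_variances_pitman_null(self):
        # Pitman-Morgan: equal method variances <=> diff uncorrelated with mean
        rng = np.random.default_rng(3)
        base = rng.normal(130, 12, 10_000)
        x = base + rng.normal(0, 7, 10_000)
        y = base + rng.normal(0, 7, 10_000)
        res = bland_altman(x, y)
        assert abs(res.pitman_r) < 0.03

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(6)
        base = rng.normal(130, 12, 5_000)
        x = base * 1.5 + rng.normal(0, 5, 5_000)
        y = base * 0.5 + rng.normal(0, 5, 5_000)
        res = bland_altman(x, y)
        assert res.pitman_r > 0.5
        assert res.pitman_p < 1e-6

    def test_minimum_pairs(self):
        with pytest.raises(ValueError, match="3 pairs"):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestDifferenceRegression:
    def test_recovers_sex_effect(self):
        rng = np.random.default_rng(21)
        n = 2000
        sex = rng.random(n) < 0.5
        df = pd.DataFrame(
            {
                "diff": 2.0 * sex + rng.normal(0, 1, n),
                "age": rng.integers(18, 80, n),
                "sex": np.where(sex, "M", "F"),
                "site": rng.choice(["A", "B"], n),
                "bmi": rng.normal(24, 4, n),
                "diabetes": rng.random(n) < 0.05,
                "smoker": rng.random(n) < 0.1,
            }
        )
        coefs = difference_regression(
            df, "diff", ["age", "sex", "site", "bmi", "diabetes", "smoker"],
            categorical=("sex", "site"),
        )
        row = coefs.loc["sex_M"]
        assert row["ci_low"] < 2.0 < row["ci_high"]
        assert row["coef"] == pytest.approx(2.0, abs=0.2)

    def test_null_covariates_quiet(self):
        rng = np.random.default_rng(22)
        n = 1000
        df = pd.DataFrame(
            {
                "diff": rng.normal(0, 5, n),
                "age": rng.integers(18, 80, n),
                "bmi": rng.normal(24, 4, n),
            }
        )
        coefs = difference_regression(df, "diff", ["age", "bmi"])
        assert (coefs.loc[["age", "bmi"], "t"].abs() < 4).all()

    def test_intercept_only_equals_mean(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame({"diff": rng.normal(3.0, 1.0, 500)})
        coefs = difference_regression(df, "diff", [])
        assert coefs.loc["const", "coef"] == pytest.approx(df["diff"].mean())

    def test_rank_deficiency_reported(self):
        rng = np.random.default_rng(24)
        n = 100
        age = rng.integers(18, 80, n).astype(float)
        df = pd.DataFrame(
            {"diff": rng.normal(0, 1, n), "age": age, "age2": 2.0 * age}
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            difference_regression(df, "diff", ["age", "age2"])


def test_pearson_correlation_basics():
    x = np.arange(50, dtype=float)
    res = pearson_correlation(x, 2 * x + 1)
    assert res["r"] == pytest.approx(1.0)
    assert res["p_value"] < 1e-10
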