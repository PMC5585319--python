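"""ROC/AUC, Youden thresholds, confusion metrics, logistic ORs, IDI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from lncsig import (auc_mann_whitney, diagnostic_metrics, evaluate_scores,
                    fit_logistic, idi, roc_auc, spearman_assoc,
                    youden_threshold)
from tests.helpers import brute_force_auc


class TestAuc:
    def test_perfect_separation(self):
        assert auc_mann_whitney([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_single_tied_pair_gets_half_credit(self):
        assert auc_mann_whitney([2.0, 2.0], [1, 0]) == 0.5

    def test_small_example(self):
        # cases {2, 4}, controls {1, 3}: 3 of 4 pairs concordant
        assert auc_mann_whitney([2, 4, 1, 3], [1, 1, 0, 0]) == 0.75

    def test_brute_force_and_sklearn_oracles(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 30)
            y = np.zeros(n, bool)
            y[: rng.integers(1, n)] = True
            s = rng.integers(0, 8, n).astype(float)   # heavy ties
            auc = auc_mann_whitney(s, y)
            assert auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_one_class_absent_is_error(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 2], [1, 1])

    def test_ci_contains_auc_and_is_clipped(self):
        rng = np.random.default_rng(1)
        s = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 20)]
        y = np.r_[np.ones(30), np.zeros(20)].astype(bool)
        res = roc_auc(s, y)
        lo, hi = res["ci"]
        assert 0.0 <= lo <= res["auc"] <= hi <= 1.0
        boot = roc_auc(s, y, ci_method="bootstrap", n_boot=200, seed=2)
        assert 0.0 <= boot["ci"][0] <= boot["ci"][1] <= 1.0

    def test_delong_p_detects_strong_signal(self):
        rng = np.random.default_rng(3)
        s = np.r_[rng.normal(2, 1, 40), rng.normal(0, 1, 40)]
        y = np.r_[np.ones(40), np.zeros(40)].astype(bool)
        assert roc_auc(s, y)["p_vs_chance"] < 1e-6


class TestYouden:
    def test_perfect_split_midpoint(self):
        res = youden_threshold([1, 2, 3, 4], [0, 0, 1, 1])
        assert res["threshold"] == pytest.approx(2.5)
        assert res["j"] == pytest.approx(1.0)

    def test_all_tied_scores_give_zero_j(self):
        res = youden_threshold([5.0] * 6, [0, 0, 0, 1, 1, 1])
        assert res["j"] == pytest.approx(0.0)

    def test_tie_break_prefers_specificity(self):
        # controls {1, 3}, cases {2, 4}: J = 0.5 at 1.5 and at 3.5;
        # the specificity-favoring tie-break picks 3.5
        res = youden_threshold([2, 4, 1, 3], [1, 1, 0, 0])
        assert res["threshold"] == pytest.approx(3.5)
        assert res["sensitivity"] == pytest.approx(0.5)
        assert res["specificity"] == pytest.approx(1.0)

    def test_exhaustive_scan_confirms_optimality(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            y = np.zeros(n, bool)
            y[: int(rng.integers(2, n - 1))] = True
            s = rng.integers(0, 6, n).astype(float)
            res = youden_threshold(s, y)
            best_j = max(
                ((s >= t) & y).sum() / y.sum()
                + (~(s >= t) & ~y).sum() / (~y).sum() - 1.0
                for t in np.r_[-np.inf, np.unique(s) - 1e-9, np.inf]
            )
            assert res["j"] == pytest.approx(best_j, abs=1e-12)


class TestDiagnosticMetrics:
    def test_printed_operating_point(self):
        """TP=23, FN=7, TN=16, FP=5 at n=30/21 gives the reported
        77% / 76% / 82% / 70% (2-decimal rounding)."""
        scores = np.r_[np.ones(23), np.zeros(7), np.ones(5), np.zeros(16)]
        labels = np.r_[np.ones(30), np.zeros(21)].astype(bool)
        rep = diagnostic_metrics(scores, labels, threshold=0.5)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (23, 7, 5, 16)
        assert round(rep.sensitivity, 2) == 0.77
        assert round(rep.specificity, 2) == 0.76
        assert round(rep.ppv, 2) == 0.82
        assert round(rep.npv, 2) == 0.70

    def test_threshold_extremes(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 1, 0, 1], bool)
        low = diagnostic_metrics(s, y, threshold=0.0)
        assert (low.sensitivity, low.specificity) == (1.0, 0.0)
        high = diagnostic_metrics(s, y, threshold=9.0)
        assert (high.sensitivity, high.specificity) == (0.0, 1.0)

    def test_identities_hold_exactly(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=40)
        y = rng.random(40) < 0.4
        y[:2] = [True, False]
        rep = diagnostic_metrics(s, y, threshold=0.1)
        assert rep.sensitivity == rep.tp / (rep.tp + rep.fn)
        assert rep.specificity == rep.tn / (rep.tn + rep.fp)
        assert rep.ppv == rep.tp / (rep.tp + rep.fp)
        assert rep.npv == rep.tn / (rep.tn + rep.fn)
        assert rep.accuracy == (rep.tp + rep.tn) / 40
        assert rep.tp + rep.fp + rep.tn + rep.fn == 40

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics([1.0, 2.0], [0, 1], float("inf"))

    def test_evaluate_scores_is_consistent(self):
        rng = np.random.default_rng(9)
        s = np.r_[rng.normal(1.5, 1, 25), rng.normal(0, 1, 25)]
        y = np.r_[np.ones(25), np.zeros(25)].astype(bool)
        rep = evaluate_scores(s, y)
        yd = youden_threshold(s, y)
        assert rep.threshold == pytest.approx(yd["threshold"])
        assert rep.youden_j == pytest.approx(yd["j"])
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]


class TestLogistic:
    def test_single_binary_covariate_matches_cross_product_ratio(self):
        # 2x2 table [[10, 4], [4, 14]] -> OR = (10*14)/(4*4) = 8.75
        y = np.r_[np.ones(14), np.zeros(18)]
        x = np.r_[np.ones(10), np.zeros(4), np.ones(4), np.zeros(14)]
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.odds_ratios[1] == pytest.approx(8.75, rel=1e-4)
        assert not fit.separated

    def test_uninformative_covariate_gives_unit_or(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.r_[np.tile([0, 1], 5), np.tile([0, 1], 5)]
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.odds_ratios[1] == pytest.approx(1.0, abs=1e-6)

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(8), np.zeros(8)]
        x = y.copy()
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.separated

    def test_rank_deficiency_is_error(self):
        y = np.r_[np.ones(6), np.zeros(6)]
        x = np.arange(12.0)
        with pytest.raises(ValueError):
            fit_logistic(y, pd.DataFrame({"a": x, "b": 2 * x}))

    def test_or_equals_exp_coefficient(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert np.allclose(fit.odds_ratios, np.exp(fit.coefficients))
        assert ((0 < fit.fitted_probabilities)
                & (fit.fitted_probabilities < 1)).all()


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_assoc([1, 2, 3, 4], [10, 20, 30, 40])["rho"] == 1.0
        assert spearman_assoc([1, 2, 3, 4], [4, 3, 2, 1])["rho"] == -1.0

    def test_rank_difference_formula(self):
        res = spearman_assoc([1, 2, 3, 4], [1, 3, 2, 4])
        assert res["rho"] == pytest.approx(0.8)   # 1 - 6*2/(4*15)

    def test_constant_vector_is_undefined(self):
        res = spearman_assoc([1, 1, 1], [1, 2, 3])
        assert not res["defined"]
        assert np.isnan(res["rho"])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_assoc([1, 2], [1, 2])


class TestIdi:
    def test_zero_on_identical_models(self):
        p = np.array([0.2, 0.8, 0.4, 0.6])
        y = np.array([0, 1, 0, 1])
        res = idi(p, p, y)
        assert res.idi == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(13)
        pn, po = rng.random(30), rng.random(30)
        y = rng.random(30) < 0.5
        y[:2] = [True, False]
        assert idi(pn, po, y).idi == pytest.approx(-idi(po, pn, y).idi)

    def test_worked_example(self):
        y = np.array([1, 1, 0, 0])
        po = np.array([0.6, 0.8, 0.4, 0.2])
        pn = np.array([0.7, 0.9, 0.3, 0.1])
        res = idi(pn, po, y)
        assert res.idi == pytest.approx(0.2)
        assert res.slope_new == pytest.approx(0.6)
        assert res.slope_old == pytest.approx(0.4)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(17)
        y = rng.random(60) < 0.5
        y[:2] = [True, False]
        po = np.clip(rng.random(60), 0.01, 0.99)
        pn = np.clip(po + 0.2 * (y - 0.5), 0.01, 0.99)
        res = idi(pn, po, y, ci_method="bootstrap", n_boot=300, seed=5)
        assert res.ci[0] <= res.idi <= res.ci[1]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            idi([1.2, 0.5], [0.5, 0.5], [0, 1])
        with pytest.raises(ValueError):
            idi([0.5, 0.5], [0.5, 0.5], [1, 1])


@given(st.lists(st.integers(0, 6), min_size=4, max_size=18),
       st.integers(1, 2**31 - 1))
def test_auc_equals_brute_force_on_arbitrary_ties(score_ints, seed):
    rng = np.random.default_rng(seed)
    s = np.asarray(score_ints, float)
    y = np.zeros(len(s), bool)
    y[rng.choice(len(s), size=max(1, len(s) // 2), replace=False)] = True
    if y.all() or not y.any():
        y[0] = ~y[0]
    assert auc_mann_whitney(s, y) == pytest.approx(brute_force_auc(s, y),
                                                   abs=1e-12)
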