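"""Metrics, ROC/AUC, McNemar and the CV experiment runner."""

import numpy as np
import pytest
from scipy import stats

from petstage.evaluate import (
    confusion_metrics,
    mcnemar,
    positive_class,
    roc_auc,
    stratified_kfold,
)


class TestStratifiedKfold:
    def test_balanced_20_samples_k10(self):
        y = np.array(["A", "B"] * 10)
        folds = stratified_kfold(y, k=10, seed=0)
        for f in range(10):
            members = y[folds == f]
            assert len(members) == 2
            assert set(members) == {"A", "B"}

    def test_partition(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["A", "B"], size=47)
        folds = stratified_kfold(y, k=5, seed=1)
        assert folds.min() == 0 and folds.max() == 4
        assert len(folds) == 47

    def test_deterministic(self):
        y = np.array(["A", "B"] * 15)
        np.testing.assert_array_equal(
            stratified_kfold(y, k=10, seed=3), stratified_kfold(y, k=10, seed=3)
        )

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array(["A", "B"] * 5), k=1)


class TestConfusionMetrics:
    def test_known_table(self):
        y_true = np.array(["P"] * 10 + ["N"] * 10)
        y_pred = np.array(["P"] * 9 + ["N"] + ["N"] * 8 + ["P"] * 2)
        m = confusion_metrics(y_true, y_pred, positive="P")
        assert m.acc == pytest.approx(0.85)
        assert m.sen == pytest.approx(0.90)
        assert m.spe == pytest.approx(0.80)

    def test_perfect_prediction(self):
        y = np.array(["P", "N", "P", "N"])
        m = confusion_metrics(y, y, positive="P")
        assert (m.acc, m.sen, m.spe) == (1.0, 1.0, 1.0)

    def test_all_positive_prediction(self):
        y_true = np.array(["P", "N", "P", "N"])
        y_pred = np.array(["P"] * 4)
        m = confusion_metrics(y_true, y_pred, positive="P")
        assert m.sen == 1.0 and m.spe == 0.0

    def test_positive_class_is_more_impaired(self):
        assert positive_class(("AD", "NC")) == "AD"
        assert positive_class(("NC", "EMCI")) == "EMCI"
        assert positive_class(("EMCI", "LMCI")) == "LMCI"


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array(["P", "P", "N", "N"])
        _, auc = roc_auc(scores, y, "P")
        assert auc == 1.0

    def test_all_ties_give_half(self):
        scores = np.zeros(10)
        y = np.array(["P", "N"] * 5)
        _, auc = roc_auc(scores, y, "P")
        assert auc == pytest.approx(0.5)

    def test_brute_force_example(self):
        # pos {0.9, 0.4}, neg {0.5, 0.1}: wins 3 of 4 pairs
        scores = np.array([0.9, 0.4, 0.5, 0.1])
        y = np.array(["P", "P", "N", "N"])
        _, auc = roc_auc(scores, y, "P")
        assert auc == pytest.approx(0.75)

    def test_threshold_curve_area_matches_pairwise(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.normal(size=60), 1)  # ties likely
        y = rng.choice(["P", "N"], size=60)
        points, auc = roc_auc(scores, y, "P")
        # integrate the ROC curve by trapezoid over sorted FPR
        order = np.argsort(points[:, 0], kind="stable")
        area = np.trapezoid(points[order, 1], points[order, 0])
        assert area == pytest.approx(auc, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array(["P", "P"]), "P")


class TestMcNemar:
    def test_symmetric_discordance_p_one(self):
        y = np.array([0] * 20)
        a = np.array([0] * 10 + [1] * 10)
        b = np.array([1] * 10 + [0] * 10)
        res = mcnemar(a, b, y)
        assert res.n01 == res.n10 == 10
        assert res.p_value == pytest.approx(1.0)

    def test_exact_branch_known_value(self):
        # n01=5, n10=15: p = 2 * sum_{i<=5} C(20,i) / 2^20
        import math

        y = np.zeros(40, dtype=int)
        a = np.concatenate([np.zeros(20), np.ones(20)])
        b = np.concatenate([np.ones(5), np.zeros(15), np.zeros(15), np.ones(5)])
        res = mcnemar(a, b, y)
        assert (res.n01, res.n10) == (5, 15)
        assert res.method == "exact_binomial"
        expected = 2 * sum(math.comb(20, i) for i in range(6)) / 2**20
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(0.0414, abs=5e-4)

    def test_chi2_branch_known_value(self):
        y = np.zeros(200, dtype=int)
        a = np.concatenate([np.zeros(50), np.ones(100), np.zeros(50)])
        b = np.concatenate([np.ones(50), np.zeros(100), np.zeros(50)])
        res = mcnemar(a, b, y)
        assert res.method == "chi2_cc"
        assert res.statistic == pytest.approx(49**2 / 150)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(49**2 / 150, 1)))

    def test_exact_branch_matches_enumeration(self):
        """Exact p equals brute-force binomial tail for all n01+n10 <= 24."""
        import math

        for n in range(1, 25):
            for n01 in range(n + 1):
                n10 = n - n01
                y = np.zeros(n, dtype=int)
                a = np.concatenate([np.zeros(n01), np.ones(n10)])
                b = np.concatenate([np.ones(n01), np.zeros(n10)])
                res = mcnemar(a, b, y)
                k = min(n01, n10)
                brute = min(1.0, 2.0 * sum(math.comb(n, i) for i in range(k + 1)) / 2**n)
                assert res.p_value == pytest.approx(brute, rel=1e-12), (n01, n10)

    def test_statsmodels_agreement(self):
        """Cross-check the exact branch against the statsmodels implementation."""
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        y = np.zeros(30, dtype=int)
        a = np.concatenate([np.zeros(4), np.ones(12), np.zeros(14)])
        b = np.concatenate([np.ones(4), np.zeros(12), np.zeros(14)])
        res = mcnemar(a, b, y)
        table = [[14, 4], [12, 0]]
        sm = sm_mcnemar(table, exact=True)
        assert res.p_value == pytest.approx(float(sm.pvalue), rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar(np.zeros(3), np.zeros(4), np.zeros(4))
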