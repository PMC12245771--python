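"""ROC/DeLong machinery, threshold metrics, decision curves, attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ivim_habitat.evaluation import (auc_delong, auc_mann_whitney,
                                     decision_curve, delong_paired_test,
                                     linear_attribution, metric_panel,
                                     permutation_importance, youden_threshold)
from ivim_habitat.modeling import SelectionConfig, cv_model_search, predict_scores


def _bruteforce_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_pair_counting_example(self):
        r = auc_delong(np.array([0.9, 0.4, 0.6, 0.2]), np.array([1, 1, 0, 0]))
        assert r.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = auc_delong(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 1, 0, 0]))
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = auc_delong(np.zeros(10), np.repeat([0, 1], 5))
        assert r.auc == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(5, 60))
    def test_matches_bruteforce_pair_counting(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc_mann_whitney(scores, labels) == \
            pytest.approx(_bruteforce_auc(scores, labels), abs=1e-12)

    def test_ci_contains_auc_and_is_clipped(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        r = auc_delong(scores, labels)
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1

    def test_ci_shrinks_with_sample_size(self):
        widths = []
        for n in (50, 200, 800):
            rng = np.random.default_rng(0)
            labels = np.repeat([0, 1], n // 2)
            scores = rng.normal(labels.astype(float), 1.0)
            r = auc_delong(scores, labels)
            widths.append(r.ci_high - r.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong(np.arange(4.0), np.ones(4))


class TestDelongPaired:
    def test_self_comparison_p_one(self, rng):
        scores = rng.normal(size=60)
        labels = np.repeat([0, 1], 30)
        z, p = delong_paired_test(scores, scores, labels)
        assert p == 1.0

    def test_antisymmetric(self, rng):
        labels = np.repeat([0, 1], 40)
        a = rng.normal(labels.astype(float), 1.0)
        b = rng.normal(size=80)
        z1, p1 = delong_paired_test(a, b, labels)
        z2, p2 = delong_paired_test(b, a, labels)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_type_i_error_calibrated(self):
        rejections = 0
        n_reps = 300
        for rep in range(n_reps):
            rng = np.random.default_rng(rep)
            labels = np.repeat([0, 1], 40)
            a, b = rng.normal(size=(2, 80))
            _, p = delong_paired_test(a, b, labels)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.08


class TestMetricPanel:
    def test_formula_arithmetic_example(self):
        # TP=2 FP=1 FN=1 TN=2
        scores = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.2])
        labels = np.array([1, 1, 0, 1, 0, 0])
        panel = metric_panel(scores, labels, threshold=0.6)
        assert (panel.tp, panel.fp, panel.fn, panel.tn) == (2, 1, 1, 2)
        assert panel.acc == pytest.approx(4 / 6)
        assert panel.mcc == pytest.approx(1 / 3)

    def test_perfect_prediction(self):
        panel = metric_panel(np.array([1.0, 1, 0, 0]), np.array([1, 1, 0, 0]),
                             threshold=0.5)
        assert (panel.acc, panel.sen, panel.spe, panel.ppv, panel.npv,
                panel.mcc) == (1, 1, 1, 1, 1, 1)

    def test_inverted_prediction_mcc_minus_one(self):
        panel = metric_panel(np.array([0.0, 0, 1, 1]), np.array([1, 1, 0, 0]),
                             threshold=0.5)
        assert panel.mcc == -1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_internal_consistency(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        p = metric_panel(scores, labels)
        n = p.tp + p.fp + p.fn + p.tn
        assert n == 30
        assert p.acc == pytest.approx((p.tp + p.tn) / n)
        if p.tp + p.fn:
            assert p.sen == pytest.approx(p.tp / (p.tp + p.fn))
        if p.tn + p.fp:
            assert p.spe == pytest.approx(p.tn / (p.tn + p.fp))
        if p.tp + p.fp:
            assert p.ppv == pytest.approx(p.tp / (p.tp + p.fp))
        if p.tn + p.fn:
            assert p.npv == pytest.approx(p.tn / (p.tn + p.fn))

    def test_youden_threshold_maximizes_j(self):
        scores = np.array([0.1, 0.2, 0.6, 0.7, 0.8])
        labels = np.array([0, 0, 1, 1, 1])
        t = youden_threshold(scores, labels)
        p = metric_panel(scores, labels, t)
        assert p.sen + p.spe - 1 == pytest.approx(1.0)


class TestDecisionCurve:
    def test_formula_example(self):
        # 10 lesions, 4 positives, all predicted positive at p_t = 0.25
        probs = np.full(10, 0.9)
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        dc = decision_curve(probs, labels, thresholds=np.array([0.25]))
        assert dc.net_benefit[0] == pytest.approx(0.4 - 0.6 / 3)

    def test_no_predicted_positive_is_zero(self):
        dc = decision_curve(np.zeros(10) + 0.01, np.repeat([0, 1], 5),
                            thresholds=np.array([0.5, 0.9]))
        assert np.allclose(dc.net_benefit, 0.0)

    def test_perfect_classifier_reaches_prevalence(self):
        labels = np.repeat([0, 1], 5)
        probs = labels.astype(float).clip(0.01, 0.99)
        dc = decision_curve(probs, labels, thresholds=np.array([0.2, 0.5, 0.9]))
        assert np.allclose(dc.net_benefit, 0.5)

    def test_treat_all_closed_form(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        probs = rng.uniform(size=50)
        dc = decision_curve(probs, labels)
        prev = labels.mean()
        expected = prev - (1 - prev) * dc.thresholds / (1 - dc.thresholds)
        assert np.allclose(dc.treat_all, expected)
        assert np.allclose(dc.treat_none, 0.0)

    def test_threshold_domain_enforced(self):
        with pytest.raises(ValueError):
            decision_curve(np.full(4, 0.5), np.array([0, 1, 0, 1]),
                           thresholds=np.array([0.0, 0.5]))


class TestAttribution:
    @pytest.fixture
    def fitted(self, rng):
        y = np.repeat([0, 1], 60)
        x = pd.DataFrame(rng.normal(size=(120, 4)),
                         columns=list("abcd"))
        x["a"] += 1.5 * y
        cfg = SelectionConfig(feature_counts=(2,), classifiers=("LR",),
                              selectors=("ANOVA",), seed=0)
        return x, y, cv_model_search(x, y, cfg)

    def test_contributions_reconstruct_scores(self, fitted):
        x, y, bundle = fitted
        contrib, baseline = linear_attribution(bundle, x)
        scores = predict_scores(bundle, x)
        assert np.allclose(contrib.sum(axis=1) + baseline, scores, atol=1e-10)

    def test_feature_at_training_mean_contributes_zero(self, fitted):
        x, y, bundle = fitted
        row = pd.DataFrame([dict(zip(bundle.features, bundle.scaler_mean))])
        contrib, _ = linear_attribution(bundle, row)
        assert np.allclose(contrib, 0.0)

    def test_doubling_coefficient_doubles_contribution(self, fitted):
        x, y, bundle = fitted
        c1, _ = linear_attribution(bundle, x)
        bundle.coef = bundle.coef * 2
        c2, _ = linear_attribution(bundle, x)
        assert np.allclose(c2, 2 * c1)

    def test_permutation_importance_ranks_signal_first(self, fitted):
        x, y, bundle = fitted
        imp = permutation_importance(bundle, x, y, repeats=5, seed=0)
        assert max(imp, key=imp.get) == "a"

    def test_permutation_importance_deterministic(self, fitted):
        x, y, bundle = fitted
        assert permutation_importance(bundle, x, y, repeats=3, seed=1) == \
            permutation_importance(bundle, x, y, repeats=3, seed=1)
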