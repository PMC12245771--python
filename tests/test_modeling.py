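"""Feature filtering, selection, and cross-validated model search."""

import numpy as np
import pandas as pd
import pytest

from ivim_habitat.evaluation import auc_mann_whitney
from ivim_habitat.modeling import (SelectionConfig, cv_model_search,
                                   filter_by_icc, icc_2_1, lasso_preselect,
                                   pcc_dedup, predict_scores, select_features,
                                   train_classifier, _relief_weights)
from ivim_habitat.phantom import CohortFeature, CohortSpec, make_synthetic_cohort
from ivim_habitat.pipeline import train_test_split_stratified

FAST_CONFIG = SelectionConfig(feature_counts=(1, 2, 4), classifiers=("LR",),
                              selectors=("ANOVA", "KW"), seed=0)


def _noise_table(n, p, seed, name="x"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"{name}{i}" for i in range(p)])


class TestIcc:
    def test_identical_raters_give_one(self, rng):
        a = rng.normal(size=50)
        assert icc_2_1(np.column_stack([a, a])) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self, rng):
        r = rng.normal(size=(1000, 2))
        assert abs(icc_2_1(r)) < 0.1

    def test_anova_table_oracle(self):
        # classic 6x2 worked example; oracle = mean-squares arithmetic
        x = np.array([[9, 2], [6, 1], [8, 4], [7, 1], [10, 5], [6, 2]], float)
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1)[:, None] - x.mean(0)[None] + grand) ** 2).sum() \
            / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_2_1(x) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        a = rng.normal(size=(40, 1))
        x = np.hstack([a, a + rng.normal(0, 0.4, size=(40, 1)) + 0.1])
        df = pd.DataFrame({"item": np.repeat(np.arange(40), 2),
                           "rater": np.tile([0, 1], 40),
                           "v": x.ravel()})
        ref = pg.intraclass_corr(df, "item", "rater", "v")
        ref_icc = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_2_1(x) == pytest.approx(ref_icc, rel=1e-9)


class TestIccFilter:
    def test_identical_replicate_keeps_all(self, rng):
        t = _noise_table(30, 5, 0)
        assert filter_by_icc(t, t.copy()) == list(t.columns)

    def test_pure_noise_replicate_column_dropped(self, rng):
        t = _noise_table(100, 3, 1)
        rep = t.copy()
        rep["x1"] = rng.normal(size=100)  # rater 2 is uncorrelated noise
        kept = filter_by_icc(t, rep)
        assert "x1" not in kept and "x0" in kept and "x2" in kept

    def test_threshold_one_with_noise_drops_all(self, rng):
        t = _noise_table(50, 4, 2)
        rep = t + rng.normal(0, 0.1, size=t.shape)
        assert filter_by_icc(t, rep, threshold=1.0) == []

    def test_column_mismatch_rejected(self):
        t = _noise_table(10, 2, 0)
        with pytest.raises(ValueError):
            filter_by_icc(t, t[["x1", "x0"]])


class TestPccDedup:
    def test_duplicated_column_leaves_one(self, rng):
        t = _noise_table(50, 3, 3)
        t["dup"] = t["x0"]
        kept = pcc_dedup(t, seed=0)
        assert ("x0" in kept) != ("dup" in kept)

    def test_orthogonal_columns_survive(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, -1, 1, -1]})
        assert pcc_dedup(t) == ["a", "b"]

    def test_surviving_set_property(self, rng):
        base = rng.normal(size=(80, 4))
        cols = {f"x{i}": base[:, i] for i in range(4)}
        for i in range(4):  # add near-duplicates
            cols[f"d{i}"] = base[:, i] + rng.normal(0, 1e-4, 80)
        t = pd.DataFrame(cols)
        kept = pcc_dedup(t, threshold=0.99, seed=1)
        corr = t[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.99

    def test_constant_columns_removed_first(self):
        t = pd.DataFrame({"c": np.ones(10), "x": np.arange(10.0)})
        assert pcc_dedup(t) == ["x"]


class TestLasso:
    def test_planted_feature_selected(self, rng):
        x = _noise_table(500, 10, 4)
        y = (rng.uniform(size=500) < 0.5).astype(int)
        x["sig"] = y * 2.0 + rng.normal(0, 1, 500)
        kept = lasso_preselect(x, y, seed=0)
        assert "sig" in kept

    def test_huge_alpha_gives_empty_set(self, rng):
        x = _noise_table(100, 5, 5)
        y = (rng.uniform(size=100) < 0.5).astype(int)
        assert lasso_preselect(x, y, alphas=(1e6,), seed=0) == []

    def test_seed_stability(self, rng):
        x = _noise_table(200, 8, 6)
        y = (rng.uniform(size=200) < 0.5).astype(int)
        assert lasso_preselect(x, y, seed=3) == lasso_preselect(x, y, seed=3)


class TestSelectors:
    @pytest.mark.parametrize("method", ["RFE", "KW", "ANOVA", "Relief"])
    def test_separating_feature_ranks_first(self, method, rng):
        n = 120
        y = np.repeat([0, 1], n // 2)
        x = _noise_table(n, 5, 7)
        x["sep"] = y * 4.0 + rng.normal(0, 0.3, n)
        assert select_features(x, y, method, 1)[0] == "sep"

    def test_kw_statistic_zero_for_identical_groups(self):
        from scipy.stats import kruskal
        x = np.array([1.0, 2, 3, 1, 2, 3])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert kruskal(x[y == 0], x[y == 1]).statistic == pytest.approx(0.0)

    def test_relief_matches_bruteforce_margins(self):
        x = np.array([[0.0, 0], [0.1, 1], [0.2, 0], [0.3, 1],
                      [5.0, 0], [5.1, 1], [5.2, 0], [5.3, 1]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        w = _relief_weights(x, y)
        # brute-force: nearest hit/miss by Euclidean distance per instance
        expected = np.zeros(2)
        for i in range(8):
            d = np.sqrt(((x - x[i]) ** 2).sum(1))
            d[i] = np.inf
            hit = np.argmin(np.where(y == y[i], d, np.inf))
            miss = np.argmin(np.where(y != y[i], d, np.inf))
            expected += np.abs(x[i] - x[miss]) - np.abs(x[i] - x[hit])
        assert np.allclose(w, expected / 8)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            select_features(_noise_table(10, 2, 0), np.zeros(10), "PCA", 1)


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["SVM", "LR"])
    def test_separable_training_auc_one(self, kind):
        x = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = train_classifier(x, y, kind)
        assert auc_mann_whitney(clf.decision_function(x), y) == 1.0

    def test_refit_same_seed_identical(self, rng):
        x = rng.normal(size=(60, 3))
        y = (rng.uniform(size=60) < 0.5).astype(int)
        a = train_classifier(x, y, "LR", seed=1)
        b = train_classifier(x, y, "LR", seed=1)
        assert np.array_equal(a.coef_, b.coef_)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((5, 1)), np.zeros(5), "LR")


class TestModelSearch:
    def test_planted_feature_wins(self, rng):
        y = np.repeat([0, 1], 100)
        x = _noise_table(200, 6, 8)
        x["sig"] = y * 1.8 + rng.normal(0, 1, 200)
        bundle = cv_model_search(x, y, FAST_CONFIG)
        assert "sig" in bundle.features
        assert bundle.cv_auc > 0.7

    def test_deterministic_under_seed(self, rng):
        y = np.repeat([0, 1], 50)
        x = _noise_table(100, 5, 9)
        b1 = cv_model_search(x, y, FAST_CONFIG)
        b2 = cv_model_search(x, y, FAST_CONFIG)
        assert b1.features == b2.features
        assert np.array_equal(b1.coef, b2.coef)
        assert b1.cv_auc == b2.cv_auc

    def test_no_test_leakage(self, rng):
        """Shuffling held-out labels cannot change held-out scores."""
        feats = [CohortFeature("s", "habitat", effects={"Y": 1.0})] + \
            [CohortFeature(f"n{i}", "habitat") for i in range(4)]
        spec = CohortSpec(n=150, prevalence={"Y": 0.5}, features=feats, seed=10)
        table, labels, _ = make_synthetic_cohort(spec)
        y = labels["Y"]
        tr, te = train_test_split_stratified(y, 0.7, 0)
        bundle = cv_model_search(table.iloc[tr], y.iloc[tr], FAST_CONFIG)
        s1 = predict_scores(bundle, table.iloc[te])
        s2 = predict_scores(bundle, table.iloc[te])  # labels never consulted
        assert np.array_equal(s1, s2)

    def test_scores_invariant_to_extra_columns(self, rng):
        y = np.repeat([0, 1], 40)
        x = _noise_table(80, 4, 11)
        bundle = cv_model_search(x, y, FAST_CONFIG)
        x_extra = x.copy()
        x_extra["unused"] = rng.normal(size=80)
        assert np.array_equal(predict_scores(bundle, x),
                              predict_scores(bundle, x_extra))

    def test_missing_feature_rejected(self, rng):
        y = np.repeat([0, 1], 30)
        x = _noise_table(60, 3, 12)
        bundle = cv_model_search(x, y, FAST_CONFIG)
        with pytest.raises(ValueError, match="missing"):
            predict_scores(bundle, x.drop(columns=bundle.features[:1]))
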