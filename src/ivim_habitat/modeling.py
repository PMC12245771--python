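"""Feature robustness filtering, selection, and cross-validated model search.

The chain mirrors common radiomics practice: drop features that are not
stable across re-segmentation (ICC(2,1) < 0.75), remove near-duplicates
(|Pearson r| > 0.99), optionally pre-select with the LASSO for large feature
families, then search selector x classifier x feature-count x regularization
combinations by stratified 5-fold cross-validated AUC.  All scaling and
selection is refit inside each training fold, so no test information leaks
into the model choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LassoCV, LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import auc_mann_whitney

__all__ = [
    "SelectionConfig",
    "ModelBundle",
    "icc_2_1",
    "filter_by_icc",
    "pcc_dedup",
    "lasso_preselect",
    "select_features",
    "train_classifier",
    "cv_model_search",
    "predict_scores",
]

SELECTOR_ORDER = ("RFE", "KW", "ANOVA", "Relief")
CLASSIFIER_ORDER = ("SVM", "LR")
LR_C_GRID = (0.01, 0.1, 1.0, 10.0)
SVM_C_GRID = (0.1, 1.0, 10.0)


@dataclass
class SelectionConfig:
    icc_threshold: float = 0.75
    pcc_threshold: float = 0.99
    lasso_alphas: tuple[float, ...] = tuple(np.logspace(np.log10(5e-3),
                                                        np.log10(5e-2), 10))
    selectors: tuple[str, ...] = SELECTOR_ORDER
    classifiers: tuple[str, ...] = CLASSIFIER_ORDER
    feature_counts: tuple[int, ...] | None = None  # default 1..min(15, p)
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.icc_threshold <= 1) or not (0 < self.pcc_threshold <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        unknown = set(self.selectors) - set(SELECTOR_ORDER)
        if unknown:
            raise ValueError(f"unknown selectors: {unknown}")

    def counts_for(self, p: int) -> tuple[int, ...]:
        if self.feature_counts is not None:
            return tuple(c for c in self.feature_counts if c <= p)
        return tuple(range(1, min(15, p) + 1))


@dataclass
class ModelBundle:
    """A fully specified fitted model: the scaler, the ordered selected
    features, the classifier with hyperparameters, and its CV search AUC."""

    endpoint: str
    family: str
    features: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    selector: str
    classifier: str
    hyperparameters: dict[str, float]
    coef: np.ndarray
    intercept: float
    cv_auc: float
    platt: tuple[float, float] | None = None  # SVM score -> probability link
    _estimator: object | None = field(default=None, repr=False)

    @property
    def is_linear(self) -> bool:
        return True  # both LR and linear-kernel SVM expose a linear score

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        return x @ self.coef + self.intercept

    def to_json(self, path: str | Path) -> None:
        payload = {
            "endpoint": self.endpoint, "family": self.family,
            "features": self.features,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "selector": self.selector, "classifier": self.classifier,
            "hyperparameters": self.hyperparameters,
            "coef": self.coef.tolist(), "intercept": self.intercept,
            "cv_auc": self.cv_auc,
            "platt": list(self.platt) if self.platt else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# robustness and redundancy

def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    *ratings* is items x raters.  From the two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-item, MSC the between-rater, and MSE the residual
    mean square.  A table with zero total variance returns 1 (perfect
    agreement on a constant).
    """
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 items and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be finite")
    grand = x.mean()
    if np.allclose(x, grand):
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if np.allclose(x, x[:, [0]]) else float("nan")
    return float((msr - mse) / denom)


def filter_by_icc(primary: pd.DataFrame, replicate: pd.DataFrame,
                  threshold: float = 0.75) -> list[str]:
    """Columns whose ICC(2,1) across the two raters meets the threshold."""
    if list(primary.columns) != list(replicate.columns):
        raise ValueError("primary and replicate tables must share columns")
    shared = primary.index.intersection(replicate.index)
    if len(shared) < 3:
        raise ValueError("replicate must cover at least 3 shared lesions")
    retained = []
    for col in primary.columns:
        ratings = np.column_stack([primary.loc[shared, col],
                                   replicate.loc[shared, col]])
        if icc_2_1(ratings) >= threshold:
            retained.append(col)
    return retained


def pcc_dedup(table: pd.DataFrame, threshold: float = 0.99,
              seed: int = 0) -> list[str]:
    """Greedy redundancy removal: for each surviving pair with
    |Pearson r| > threshold, randomly drop one member (seeded).  Constant
    columns are removed first."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    rng = np.random.default_rng(seed)
    cols = list(table.columns)
    alive = {c for c in cols if table[c].std() > 0}
    corr = table.corr().abs()
    for i, ci in enumerate(cols):
        if ci not in alive:
            continue
        for cj in cols[i + 1:]:
            if cj not in alive:
                continue
            if corr.loc[ci, cj] > threshold:
                alive.discard(ci if rng.random() < 0.5 else cj)
                if ci not in alive:
                    break
    return [c for c in cols if c in alive]


def lasso_preselect(x: pd.DataFrame, y: np.ndarray,
                    alphas: tuple[float, ...] | None = None,
                    seed: int = 0) -> list[str]:
    """L1-penalized pre-selection over the alpha grid, alpha chosen by
    cross-validated prediction error; returns the nonzero-coefficient
    features (possibly empty)."""
    alphas = alphas if alphas is not None else SelectionConfig().lasso_alphas
    xs = (x - x.mean()) / x.std().replace(0, 1.0)
    model = LassoCV(alphas=list(alphas), cv=5, random_state=seed)
    model.fit(xs.to_numpy(), np.asarray(y, dtype=float))
    return [c for c, w in zip(x.columns, model.coef_) if w != 0.0]


# ---------------------------------------------------------------------------
# per-fold selection

def _relief_weights(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Relief weights: for every instance, the margin between its distance to
    the nearest miss and the nearest hit, accumulated per feature."""
    n, p = x.shape
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(p)
    for i in range(n):
        same = y == y[i]
        same[i] = False
        if not same.any() or same.all():
            continue
        hit = np.argmin(np.where(same, d2[i], np.inf))
        miss = np.argmin(np.where(~same, d2[i], np.inf))
        w += np.abs(x[i] - x[miss]) - np.abs(x[i] - x[hit])
    return w / n


def _rank_features(x: np.ndarray, y: np.ndarray, method: str,
                   seed: int = 0) -> np.ndarray:
    """Full preference ordering of feature indices (best first)."""
    n, p = x.shape
    if method == "RFE":
        # iterative elimination by smallest |coefficient| of an L2 logistic fit
        remaining = list(range(p))
        eliminated: list[int] = []
        while len(remaining) > 1:
            clf = LogisticRegression(max_iter=1000, random_state=seed)
            clf.fit(x[:, remaining], y)
            worst = int(np.argmin(np.abs(clf.coef_[0])))
            eliminated.append(remaining.pop(worst))
        return np.array(remaining + eliminated[::-1])
    if method == "KW":
        scores = np.array([
            stats.kruskal(x[y == 0, j], x[y == 1, j]).statistic
            if (np.ptp(x[:, j]) > 0) else 0.0
            for j in range(p)
        ])
        return np.argsort(-scores, kind="stable")
    if method == "ANOVA":
        f, _ = f_classif(x, y)
        return np.argsort(-np.nan_to_num(f), kind="stable")
    if method == "Relief":
        return np.argsort(-_relief_weights(x, y), kind="stable")
    raise ValueError(f"unknown selection method {method!r}")


def select_features(x: pd.DataFrame, y: np.ndarray, method: str,
                    count: int, seed: int = 0) -> list[str]:
    """Top-*count* features under the given selector, best first."""
    if count > x.shape[1]:
        raise ValueError("count exceeds the number of columns")
    order = _rank_features(x.to_numpy(dtype=float), np.asarray(y), method, seed)
    return [x.columns[j] for j in order[:count]]


def train_classifier(x: np.ndarray, y: np.ndarray, kind: str,
                     c: float = 1.0, seed: int = 0):
    """Fit an L2 logistic regression or a linear soft-margin SVM."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if kind == "LR":
        clf = LogisticRegression(C=c, max_iter=1000, random_state=seed)
    elif kind == "SVM":
        clf = SVC(kernel="linear", C=c, random_state=seed)
    else:
        raise ValueError(f"unknown classifier {kind!r}")
    clf.fit(x, y)
    return clf


# ---------------------------------------------------------------------------
# CV model search

def _c_grid(kind: str) -> tuple[float, ...]:
    return LR_C_GRID if kind == "LR" else SVM_C_GRID


def cv_model_search(x: pd.DataFrame, y: np.ndarray | pd.Series,
                    config: SelectionConfig, endpoint: str = "endpoint",
                    family: str = "features",
                    use_lasso: bool = False) -> ModelBundle:
    """Stratified K-fold search over selector x count x classifier x C.

    Scaling, (optional) LASSO pre-selection, and feature ranking are all
    refit inside every training fold; the winning combination (highest mean
    CV AUC; ties to fewer features, then selector order, then classifier
    order) is refit on the full table.
    """
    y = np.asarray(y)
    cols = list(x.columns)
    counts = config.counts_for(len(cols))
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    combos: dict[tuple, list[float]] = {}
    xv = x.to_numpy(dtype=float)

    for train_idx, val_idx in skf.split(xv, y):
        xt, yt = xv[train_idx], y[train_idx]
        xvl, yvl = xv[val_idx], y[val_idx]
        mean, sd = xt.mean(axis=0), xt.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        zt, zv = (xt - mean) / sd, (xvl - mean) / sd

        active = np.arange(len(cols))
        if use_lasso:
            kept = lasso_preselect(
                pd.DataFrame(zt, columns=cols), yt,
                config.lasso_alphas, config.seed)
            if kept:
                active = np.array([cols.index(c) for c in kept])
        for selector in config.selectors:
            order = _rank_features(zt[:, active], yt, selector, config.seed)
            ranked = active[order]
            for count in counts:
                if count > ranked.size:
                    continue
                sub = ranked[:count]
                for classifier in config.classifiers:
                    for c in _c_grid(classifier):
                        clf = train_classifier(zt[:, sub], yt, classifier, c,
                                               config.seed)
                        scores = clf.decision_function(zv[:, sub])
                        auc = auc_mann_whitney(scores, yvl)
                        combos.setdefault((selector, count, classifier, c),
                                          []).append(auc)

    def sort_key(item):
        (selector, count, classifier, c), aucs = item
        return (-float(np.mean(aucs)), count,
                config.selectors.index(selector),
                config.classifiers.index(classifier), c)

    (selector, count, classifier, c), aucs = min(combos.items(), key=sort_key)
    cv_auc = float(np.mean(aucs))

    # refit on the full table
    mean, sd = xv.mean(axis=0), xv.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (xv - mean) / sd
    active = np.arange(len(cols))
    if use_lasso:
        kept = lasso_preselect(pd.DataFrame(z, columns=cols), y,
                               config.lasso_alphas, config.seed)
        if kept:
            active = np.array([cols.index(cname) for cname in kept])
    order = _rank_features(z[:, active], y, selector, config.seed)
    sub = active[order[: min(count, order.size)]]
    clf = train_classifier(z[:, sub], y, classifier, c, config.seed)

    platt = None
    if classifier == "SVM":
        # logistic link from decision scores to probabilities, fitted on
        # the training scores (decision-curve analysis needs probabilities)
        train_scores = clf.decision_function(z[:, sub]).reshape(-1, 1)
        link = LogisticRegression(max_iter=1000, random_state=config.seed)
        link.fit(train_scores, y)
        platt = (float(link.coef_[0, 0]), float(link.intercept_[0]))

    return ModelBundle(
        endpoint=endpoint, family=family,
        features=[cols[j] for j in sub],
        scaler_mean=mean[sub], scaler_sd=sd[sub],
        selector=selector, classifier=classifier,
        hyperparameters={"C": c},
        coef=np.asarray(clf.coef_[0], dtype=float),
        intercept=float(clf.intercept_[0]),
        cv_auc=cv_auc, platt=platt, _estimator=clf,
    )


def predict_scores(bundle: ModelBundle, x: pd.DataFrame) -> np.ndarray:
    """Decision scores (monotone in predicted risk) for new lesions."""
    missing = [c for c in bundle.features if c not in x.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    z = (x[bundle.features].to_numpy(dtype=float) - bundle.scaler_mean) \
        / bundle.scaler_sd
    return bundle.decision_scores(z)


def predict_probabilities(bundle: ModelBundle, x: pd.DataFrame) -> np.ndarray:
    """Probabilities for decision-curve analysis: the logistic output for LR,
    or the training-fitted logistic link of the SVM decision score."""
    s = predict_scores(bundle, x)
    if bundle.classifier == "LR":
        return 1.0 / (1.0 + np.exp(-s))
    if bundle.platt is None:
        raise ValueError("SVM bundle lacks a probability link")
    a, b = bundle.platt
    return 1.0 / (1.0 + np.exp(-(a * s + b)))
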