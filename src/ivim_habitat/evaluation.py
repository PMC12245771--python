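"""Discrimination and clinical-utility evaluation of binary risk models.

AUCs are computed by the Mann-Whitney statistic (ties count one half), with
variance and paired-model comparison from DeLong's structural components.
Threshold metrics (accuracy, sensitivity, specificity, PPV, NPV, MCC) derive
from a single confusion matrix at a Youden-optimal threshold frozen on
training scores.  Decision-curve analysis reports the net benefit

    NB(p_t) = TP/N - FP/N * p_t / (1 - p_t)

against the treat-all and treat-none references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "MetricPanel",
    "DecisionCurve",
    "auc_mann_whitney",
    "auc_delong",
    "delong_paired_test",
    "youden_threshold",
    "metric_panel",
    "decision_curve",
    "linear_attribution",
    "permutation_importance",
]


@dataclass
class RocResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class MetricPanel:
    threshold: float
    acc: float
    sen: float
    spe: float
    ppv: float
    npv: float
    mcc: float
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive pair counting via midranks; ties count one half."""
    auc, _, _ = _delong_components(scores, labels)
    return auc


def auc_delong(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """AUC with DeLong variance and a 95% normal-approximation CI."""
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    lo = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
    hi = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = labels[order]
    tpr = np.concatenate([[0.0], np.cumsum(y) / max(y.sum(), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(1 - y) / max((1 - y).sum(), 1)])
    return RocResult(auc=auc, variance=float(var), ci_low=lo, ci_high=hi,
                     fpr=fpr, tpr=tpr)


def delong_paired_test(scores_a: np.ndarray, scores_b: np.ndarray,
                       labels: np.ndarray) -> tuple[float, float]:
    """DeLong's paired test of two correlated AUCs on the same lesions.

    Returns (z, two-sided p).  When the difference has zero variance and the
    AUCs are equal (e.g. a model compared with itself), p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _confusion(scores: np.ndarray, labels: np.ndarray, threshold: float):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score threshold maximizing sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    best_t, best_j = scores.min(), -np.inf
    for t in np.unique(scores):
        tp, fp, fn, tn = _confusion(scores, labels, t)
        sen = tp / (tp + fn) if tp + fn else 0.0
        spe = tn / (tn + fp) if tn + fp else 0.0
        j = sen + spe - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def metric_panel(scores: np.ndarray, labels: np.ndarray,
                 threshold: float | None = None) -> MetricPanel:
    """Confusion-matrix metrics at a threshold (Youden-optimal on the given
    scores when none is supplied; for honest test reporting freeze the
    threshold on training scores first)."""
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    tp, fp, fn, tn = _confusion(scores, labels, threshold)
    total = tp + fp + fn + tn
    acc = (tp + tn) / total
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricPanel(threshold=float(threshold), acc=acc, sen=sen, spe=spe,
                       ppv=ppv, npv=npv, mcc=float(mcc),
                       tp=tp, fp=fp, fn=fn, tn=tn)


def decision_curve(probabilities: np.ndarray, labels: np.ndarray,
                   thresholds: np.ndarray | None = None) -> DecisionCurve:
    """Net benefit of treating lesions with predicted probability >= p_t."""
    probabilities = np.asarray(probabilities, dtype=float)
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    labels = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = labels.size
    prevalence = labels.mean()
    nb = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        tp, fp, _, _ = _confusion(probabilities, labels, pt)
        nb[i] = tp / n - fp / n * pt / (1 - pt)
    treat_all = prevalence - (1 - prevalence) * thresholds / (1 - thresholds)
    return DecisionCurve(thresholds=thresholds, net_benefit=nb,
                         treat_all=treat_all,
                         treat_none=np.zeros_like(thresholds))


def linear_attribution(bundle, x) -> tuple[np.ndarray, float]:
    """Exact per-feature contributions of a linear model.

    For standardized inputs z, contribution(i, j) = w_j * z_ij and
    contributions plus the intercept reconstruct the decision score; a lesion
    sitting at the training mean of a feature receives zero contribution from
    it.  Returns (contributions [lesions x features], baseline intercept).
    """
    import pandas as pd
    if isinstance(x, pd.DataFrame):
        z = (x[bundle.features].to_numpy(dtype=float) - bundle.scaler_mean) \
            / bundle.scaler_sd
    else:
        z = np.asarray(x, dtype=float)
    return z * bundle.coef[None, :], float(bundle.intercept)


def permutation_importance(bundle, x, y, repeats: int = 10,
                           seed: int = 0) -> dict[str, float]:
    """Mean AUC drop when each selected feature column is permuted."""
    from .modeling import predict_scores  # local import avoids a cycle
    rng = np.random.default_rng(seed)
    base = auc_mann_whitney(predict_scores(bundle, x), y)
    out: dict[str, float] = {}
    for feat in bundle.features:
        drops = []
        for _ in range(repeats):
            xp = x.copy()
            xp[feat] = rng.permutation(xp[feat].to_numpy())
            drops.append(base - auc_mann_whitney(predict_scores(bundle, xp), y))
        out[feat] = float(np.mean(drops))
    return out
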