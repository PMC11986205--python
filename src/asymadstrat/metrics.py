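"""Shared classification metrics.

`roc_auc` is a rank-based implementation (Mann-Whitney U normalization with
midranks for ties) kept independent of any library ROC routine so it can be
checked against brute-force concordant-pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortError


class UndefinedMetricError(CohortError):
    """Metric undefined for the given inputs (e.g. single-class AUC)."""


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via midrank normalization.

    Equals the probability that a random positive outranks a random
    negative, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = y == y.max()
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0 or y.max() == y.min():
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_counts(y_true, y_pred) -> dict[str, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return {
        "tp": int(((y_true == 1) & (y_pred == 1)).sum()),
        "tn": int(((y_true == 0) & (y_pred == 0)).sum()),
        "fp": int(((y_true == 0) & (y_pred == 1)).sum()),
        "fn": int(((y_true == 1) & (y_pred == 0)).sum()),
    }


def rates_from_confusion(c: dict[str, int]) -> dict[str, float]:
    tp, tn, fp, fn = c["tp"], c["tn"], c["fp"], c["fn"]
    n = tp + tn + fp + fn
    out = {"accuracy": (tp + tn) / n if n else float("nan")}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
    out["recall"] = out["sensitivity"]
    out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    out["precision"] = tp / (tp + fp) if tp + fp else float("nan")
    return out


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Proportion as a percent, rounded half-up to `decimals` places."""
    if total <= 0:
        raise CohortError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(
        q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Per-evaluation classification metrics."""

    confusion: dict[str, int]
    rates: dict[str, float]
    roc_auc: float
    fold_ids: list[np.ndarray] | None = None
    fold_aucs: list[float] | None = None
    mean_fpr: np.ndarray | None = None
    mean_tpr: np.ndarray | None = None
    tpr_se: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for k, v in self.rates.items():
            if np.isfinite(v) and not 0.0 <= v <= 1.0 + 1e-12:
                raise CohortError(f"rate {k} outside [0, 1]: {v}")


def evaluate_predictions(y_true, y_pred, scores) -> MetricsReport:
    c = confusion_counts(y_true, y_pred)
    return MetricsReport(c, rates_from_confusion(c), roc_auc(scores, y_true))


def kfold_cv(X, y, k: int = 6, seed: int = 0,
             C: float = 1.0) -> MetricsReport:
    """Stratified k-fold logistic-regression CV.

    Out-of-fold predictions are pooled into a single confusion matrix; the
    mean ROC curve is computed on a common false-positive-rate grid with a
    standard-error band across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if k >= n:
        raise CohortError(f"k={k} too large for n={n}; use a smaller k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(n, dtype=int)
    y_score = np.empty(n, dtype=float)
    fold_ids, fold_aucs, tprs = [], [], []
    grid = np.linspace(0.0, 1.0, 101)
    for train_idx, test_idx in skf.split(X, y):
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(X[train_idx], y[train_idx])
        s = clf.decision_function(X[test_idx])
        y_score[test_idx] = s
        y_pred[test_idx] = clf.predict(X[test_idx])
        fold_ids.append(test_idx)
        fold_aucs.append(roc_auc(s, y[test_idx]))
        fpr, tpr = _roc_points(s, y[test_idx])
        tprs.append(np.interp(grid, fpr, tpr))
    tprs = np.asarray(tprs)
    c = confusion_counts(y, y_pred)
    return MetricsReport(
        confusion=c, rates=rates_from_confusion(c),
        roc_auc=roc_auc(y_score, y),
        fold_ids=fold_ids, fold_aucs=fold_aucs,
        mean_fpr=grid, mean_tpr=tprs.mean(axis=0),
        tpr_se=tprs.std(axis=0, ddof=1) / np.sqrt(k), seed=seed)


def _roc_points(scores, y) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order] == y.max()
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return fpr, tpr
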