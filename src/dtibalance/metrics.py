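"""Evaluation metrics: confusion-table statistics, MSE, and rank-based AUC.

Zero-denominator conventions: precision (and recall/F1) fall back to 0 with
a warning when their denominator is empty, and MCC is 0 whenever any factor
under its square root vanishes. This keeps fold averages NaN-free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion counts are all zero")


@dataclass
class MetricsReport:
    """Scalar metrics, optionally with the per-fold values they average."""

    accuracy: float = math.nan
    precision: float = math.nan
    recall: float = math.nan
    f1: float = math.nan
    mcc: float = math.nan
    mse: float = math.nan
    auc: float = math.nan
    per_fold: list["MetricsReport"] = field(default_factory=list)

    FIELDS = ("accuracy", "precision", "recall", "f1", "mcc", "mse", "auc")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}

    @classmethod
    def mean_of(cls, folds: list["MetricsReport"]) -> "MetricsReport":
        """Arithmetic mean over folds, skipping NaN entries per metric."""
        out = cls(per_fold=list(folds))
        for name in cls.FIELDS:
            vals = [getattr(f, name) for f in folds if not math.isnan(getattr(f, name))]
            setattr(out, name, sum(vals) / len(vals) if vals else math.nan)
        return out


def confusion_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, F1 and MCC from a confusion table."""
    total = c.tp + c.tn + c.fp + c.fn
    accuracy = (c.tp + c.tn) / total

    if c.tp + c.fp == 0:
        warnings.warn("precision undefined (tp+fp=0); reporting 0", stacklevel=2)
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("recall undefined (tp+fn=0); reporting 0", stacklevel=2)
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * recall * precision / (recall + precision)

    denom = (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1, mcc=mcc
    )


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truth and predictions")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def mse(truth, pred) -> float:
    """Mean squared error (1/n) * sum (Y_i - Yhat_i)^2."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError(
            f"length mismatch: truth has {truth.shape}, pred has {pred.shape}"
        )
    if truth.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((truth - pred) ** 2))


def roc_auc(labels, scores) -> float:
    """AUC via the rank (Mann-Whitney) formulation with midrank ties."""
    auc, _ = roc_auc_with_curve(labels, scores)
    return auc


def roc_auc_with_curve(labels, scores) -> tuple[float, np.ndarray]:
    """AUC plus the ROC curve points (fpr, tpr) for plotting.

    The AUC is computed from ranks: U / (n_pos * n_neg), where U is the
    Mann-Whitney statistic of positive scores against negatives, with tied
    scores receiving midranks.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores length mismatch")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # midranks for ties
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))

    # Curve: sweep thresholds from high to low over distinct score values.
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], sorted_labels.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return auc, np.column_stack([fpr, tpr])
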