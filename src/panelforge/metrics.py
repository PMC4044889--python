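"""Confusion-matrix statistics, ROC curves and AUC.

The positive class is cancer throughout.  Tied scores are grouped into a
single ROC vertex (a diagonal segment), which makes the trapezoidal AUC
exactly equal to the half-tie Mann-Whitney pair-count statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ROCCurve",
    "UndefinedMetricsError",
    "confusion_metrics",
    "metrics_percent",
    "confusion_from_scores",
    "roc_curve",
    "auc",
    "auc_score",
]


class UndefinedMetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, precision, accuracy as proportions in [0, 1].

    A metric whose denominator is zero is reported as ``None`` rather than
    0.  An all-zero matrix raises :class:`UndefinedMetricsError`.
    """
    if cm.total == 0:
        raise UndefinedMetricsError("all-zero confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "precision": ratio(cm.tp, cm.tp + cm.fp),
        "accuracy": (cm.tp + cm.tn) / cm.total,
    }


def metrics_percent(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Display form: percentages rounded to two decimals (e.g. 86.84)."""
    return {
        k: (None if v is None else round(100.0 * v, 2))
        for k, v in confusion_metrics(cm).items()
    }


def confusion_from_scores(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.0
) -> ConfusionMatrix:
    """Threshold scores into a confusion matrix.

    ``labels`` are 1 = cancer, 0 = control.  Predicted cancer iff
    score > threshold (a tie predicts control).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores > threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        fpr, tpr = np.asarray(self.fpr), np.asarray(self.tpr)
        if fpr.shape != tpr.shape or fpr.ndim != 1:
            raise ValueError("fpr/tpr must be matching 1-D arrays")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing")
        if not (fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1):
            raise ValueError("curve must run from (0,0) to (1,1)")


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve from a descending threshold sweep over distinct scores.

    Tied scores contribute a single vertex.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")

    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # keep the last index of each run of equal scores
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return ROCCurve(fpr, tpr, thresholds)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Convenience: AUC straight from scores and 0/1 labels."""
    return auc(roc_curve(scores, labels))
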