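"""Binary-classification evaluation: confusion counts, accuracy,
sensitivity, specificity, F1, the Matthews correlation coefficient, and
ROC curves.

Zero-denominator conventions: MCC is 0 whenever any factor of its
denominator is 0, and any 0/0 ratio metric is reported as 0.  These
degenerate cases are documented and tested rather than raised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class EvaluationError(ValueError):
    """Raised when an evaluation request is ill-posed."""


@dataclass
class ConfusionCounts:
    """TP / TN / FP / FN for SNARE (1) vs. non-SNARE (0) decisions."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN from parallel binary vectors."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape or labels.ndim != 1:
        raise EvaluationError("labels and predictions must be equal-length 1-D")
    if labels.size < 1:
        raise EvaluationError("need at least one evaluated sequence")
    return ConfusionCounts(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TN*TP - FN*FP) / sqrt((FP+TP)(FN+TP)(FP+TN)(FN+TN)); 0 by convention
    when any denominator factor vanishes.
    """
    denom = ((c.fp + c.tp) * (c.fn + c.tp) * (c.fp + c.tn) * (c.fn + c.tn))
    if denom == 0:
        return 0.0
    return (c.tn * c.tp - c.fn * c.fp) / math.sqrt(denom)


def basic_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity (recall), specificity, F1; 0/0 -> 0."""

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "f1": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def roc(labels: Sequence[int], scores: Sequence[float]):
    """ROC points and trapezoid AUC by sweeping all distinct thresholds.

    Points run from (0, 0) to (1, 1); tied scores share a threshold.
    Requires both classes present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise EvaluationError("labels and scores must be equal-length 1-D")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs both classes present in labels")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep only the last index of each tied-score run
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos, 1.0]
    fpr = np.r_[0.0, fps[distinct] / n_neg, 1.0]
    points = list(zip(fpr.tolist(), tpr.tolist()))
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class MetricsReport:
    """All reported metrics for one evaluation run."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    roc_points: list
    auc: float

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1,
            "mcc": round(self.mcc, 4), "auc": self.auc,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(labels: Sequence[int], scores: Sequence[float],
             threshold: float = 0.5) -> MetricsReport:
    """Full report from true labels and class-1 probabilities."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    predictions = (scores >= threshold).astype(int)
    c = confusion(labels, predictions)
    basics = basic_metrics(c)
    points, auc = roc(labels, scores)
    return MetricsReport(
        counts=c,
        accuracy=basics["accuracy"],
        sensitivity=basics["sensitivity"],
        specificity=basics["specificity"],
        f1=basics["f1"],
        mcc=mcc(c),
        roc_points=points,
        auc=auc,
    )
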