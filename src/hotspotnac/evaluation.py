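"""Binary-classification metrics for NAC-response prediction.

pCR is the positive class throughout. Accuracy, the true/false positive
rates, precision, recall and F1 follow the standard confusion-matrix
definitions:

    accuracy = (TP + TN) / (TP + FN + TN + FP)
    TPR = TP / (TP + FN),  FPR = FP / (FP + TN)
    precision = TP / (TP + FP),  recall = TPR
    F1 = 2 * precision * recall / (precision + recall)

ROC AUC is the Mann-Whitney rank statistic — the probability that a
random positive outscores a random negative, ties counted half — which
equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import ValidationError

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "metrics",
    "roc_auc",
    "report",
]

POSITIVE_LABEL = "pCR"
NEGATIVE_LABEL = "RD"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with pCR positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def row_normalized(self) -> np.ndarray:
        """Rows = true class (pCR, RD), columns = predicted (pCR, RD);
        each row divided by its total where positive."""
        mat = np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, mat / sums, 0.0)
        return out


def confusion(
    y_true, y_pred, positive: str = POSITIVE_LABEL
) -> ConfusionCounts:
    """Confusion counts from label sequences (pCR positive by default)."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.size == 0:
        raise ValidationError("y_true is empty")
    if t.shape != p.shape:
        raise ValidationError(
            f"length mismatch: {t.shape[0]} true vs {p.shape[0]} predicted labels"
        )
    tpos = t == positive
    ppos = p == positive
    return ConfusionCounts(
        tp=int((tpos & ppos).sum()),
        fp=int((~tpos & ppos).sum()),
        tn=int((~tpos & ~ppos).sum()),
        fn=int((tpos & ~ppos).sum()),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, TPR, FPR, precision, recall and F1 from confusion counts.

    Zero-denominator conventions: precision is 0 (with a warning) when
    nothing was predicted positive; F1 is 0 when precision + recall = 0;
    TPR (FPR) is 0 when no positives (negatives) exist.
    """
    if counts.total == 0:
        raise ValidationError("confusion counts are all zero")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    accuracy = (tp + tn) / counts.total
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        warnings.warn(
            "no positive predictions; precision set to 0 by convention",
            UserWarning,
            stacklevel=2,
        )
        precision = 0.0
    recall = tpr
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "accuracy": accuracy,
        "tpr": tpr,
        "fpr": fpr,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def roc_auc(y_true, scores, positive: str = POSITIVE_LABEL) -> float:
    """Area under the ROC curve from labels and positive-class scores."""
    t = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValidationError("labels and scores must have equal length")
    y = t == positive
    if y.all() or not y.any():
        raise ValidationError(
            "ROC AUC requires both classes present in y_true"
        )
    return float(roc_auc_score(y.astype(int), s))


@dataclass
class EvaluationReport:
    """Full metric panel at one aggregation level (patch or patient)."""

    level: str
    counts: ConfusionCounts
    accuracy: float
    tpr: float
    fpr: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    confusion_row_normalized: list[list[float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "accuracy": self.accuracy,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "confusion_row_normalized": self.confusion_row_normalized,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def report(level: str, y_true, y_pred, scores=None) -> EvaluationReport:
    """Evaluate predictions at one level into a single report object.

    ``scores`` (positive-class scores aligned with ``y_true``) are
    optional; without them the AUC field is None.
    """
    if level not in ("patch", "patient"):
        raise ValidationError(f"level must be 'patch' or 'patient', got {level!r}")
    counts = confusion(y_true, y_pred)
    m = metrics(counts)
    auc = None
    if scores is not None:
        auc = roc_auc(y_true, scores)
    return EvaluationReport(
        level=level,
        counts=counts,
        auc=auc,
        confusion_row_normalized=counts.row_normalized().tolist(),
        **m,
    )
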