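"""Confusion-matrix construction and evaluation metrics.

Positive class is 1 (pneumonia). Ratio metrics are computed with exact
rational arithmetic on the integer cell counts before conversion to float,
so printed worked examples are reproduced to the last digit. A ratio whose
denominator is zero is reported as ``None`` (an undefined marker) with a
logged warning rather than raising, so batch/ablation reports never abort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "accuracy",
    "precision",
    "recall",
    "sensitivity",
    "specificity",
    "f1",
    "report_from_cm",
    "compute_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with positive class = pneumonia (label 1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FP/TN/FN from binary label vectors of equal length."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.size}, y_pred has {y_pred.size}")
    if y_true.size < 1:
        raise ValueError("need at least one sample")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        logger.warning("%s undefined: zero denominator", name)
        return None
    return float(Fraction(num, den))


def accuracy(cm: ConfusionMatrix) -> float | None:
    """(TP+TN) / total."""
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy")


def precision(cm: ConfusionMatrix) -> float | None:
    """TP / (TP+FP)."""
    return _ratio(cm.tp, cm.tp + cm.fp, "precision")


def recall(cm: ConfusionMatrix) -> float | None:
    """TP / (TP+FN); the true-positive rate."""
    return _ratio(cm.tp, cm.tp + cm.fn, "recall")


#: sensitivity is the same formula as recall
sensitivity = recall


def specificity(cm: ConfusionMatrix) -> float | None:
    """TN / (TN+FP); the true-negative rate."""
    return _ratio(cm.tn, cm.tn + cm.fp, "specificity")


def f1(cm: ConfusionMatrix) -> float | None:
    """Harmonic mean of precision and recall: 2TP / (2TP+FP+FN)."""
    return _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1")


@dataclass
class MetricsReport:
    """All ratio metrics plus the underlying confusion matrix."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    cm: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "tp": self.cm.tp,
            "fp": self.cm.fp,
            "tn": self.cm.tn,
            "fn": self.cm.fn,
        }

    def to_json(self, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def report_from_cm(cm: ConfusionMatrix) -> MetricsReport:
    return MetricsReport(
        accuracy=accuracy(cm),
        precision=precision(cm),
        recall=recall(cm),
        specificity=specificity(cm),
        f1=f1(cm),
        cm=cm,
    )


def compute_report(y_true, y_pred) -> MetricsReport:
    """Confusion matrix + metrics in one call."""
    return report_from_cm(confusion_matrix(y_true, y_pred))
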