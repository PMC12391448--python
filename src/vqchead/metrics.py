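"""Binary-classification evaluation: confusion counts, balanced accuracy,
sensitivity/specificity and ROC/AUC.

Balanced accuracy is the mean of sensitivity (recall on the positive,
here malignant, class) and specificity (recall on the negative class) —
the headline metric for imbalanced screening data, where plain accuracy
rewards always predicting the majority class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["MetricsReport", "confusion", "binary_metrics", "roc_points_auc",
           "evaluate_scores"]


class UndefinedMetricError(ValueError):
    """A metric's denominator class is empty (no positives or no negatives)."""


def _check_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr).ravel()
    if not np.all(np.isin(a, (0, 1))):
        raise ValueError(f"{name} must be binary 0/1, got values {np.unique(a)}")
    return a.astype(int)


def confusion(labels, predictions) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) counts; positive class is label 1."""
    y = _check_binary(labels, "labels")
    p = _check_binary(predictions, "predictions")
    if y.size != p.size:
        raise ValueError(f"length mismatch: {y.size} labels vs {p.size} predictions")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return tp, tn, fp, fn


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, balanced accuracy) from confusion counts."""
    if tp + fn == 0:
        raise UndefinedMetricError(
            "sensitivity undefined: no positive samples (TP + FN = 0)")
    if tn + fp == 0:
        raise UndefinedMetricError(
            "specificity undefined: no negative samples (TN + FP = 0)")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, 0.5 * (sens + spec)


def roc_points_auc(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC curve (FPR, TPR per threshold) and trapezoid AUC.

    The AUC equals the normalized Mann-Whitney U statistic (pairs where
    the positive outscores the negative, ties counted one half).
    """
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain NaN or Inf")
    if y.size != s.size:
        raise ValueError(f"length mismatch: {y.size} labels vs {s.size} scores")
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("ROC undefined: only one class present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class MetricsReport:
    """Confusion counts plus the derived screening metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    bacc: float
    auc: float
    roc: list = field(default_factory=list, repr=False)

    def to_dict(self, include_roc: bool = False) -> dict:
        d = {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
             "sensitivity": self.sensitivity, "specificity": self.specificity,
             "bacc": self.bacc, "auc": self.auc}
        if include_roc:
            d["roc"] = [[float(a), float(b)] for a, b in self.roc]
        return d

    def to_json(self, include_roc: bool = False) -> str:
        return json.dumps(self.to_dict(include_roc), indent=2)

    def __str__(self) -> str:
        return (f"BACC={self.bacc:.4f}  AUC={self.auc:.4f}  "
                f"SEN={self.sensitivity:.4f}  SPE={self.specificity:.4f}  "
                f"(TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn})")


def evaluate_scores(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report from soft scores: threshold for counts, sweep for ROC."""
    s = np.asarray(scores, dtype=float).ravel()
    preds = (s >= threshold).astype(int)
    tp, tn, fp, fn = confusion(labels, preds)
    sens, spec, bacc = binary_metrics(tp, tn, fp, fn)
    roc, auc = roc_points_auc(labels, s)
    return MetricsReport(tp, tn, fp, fn, sens, spec, bacc, auc, roc)
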