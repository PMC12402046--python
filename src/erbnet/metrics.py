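"""Confusion-matrix metrics, ROC curves and AUC.

Sensitivity = TP/(TP+FN), specificity = TN/(FP+TN), precision =
TP/(TP+FP), accuracy = (TP+TN)/total, F1 = harmonic mean of precision and
sensitivity.  A metric with an empty denominator is reported as NaN (an
explicit "undefined" marker) rather than 0 or an exception, so reports
stay honest on degenerate sets.  Predictions are thresholded with the
``prob >= threshold`` rule (ties count positive).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn import metrics as _skm

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "compute_metrics", "roc_curve", "auc", "evaluate_probs"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Metric bundle; NaN marks a metric undefined on this sample set."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    auc: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int)


def confusion_counts(probs, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold probabilities and count the confusion-matrix cells."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = _check_binary(labels)
    if probs.shape != labels.shape:
        raise ValueError(f"length mismatch: {probs.shape} probs vs {labels.shape} labels")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Compute the metric bundle from confusion counts (AUC left unset)."""
    if c.total < 1:
        raise ValueError("need at least one decision")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.fp + c.tn)
    prec = _ratio(c.tp, c.tp + c.fp)
    acc = (c.tp + c.tn) / c.total
    if np.isnan(prec) or np.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricsReport(sens, spec, prec, acc, f1)


def roc_curve(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (fpr, tpr), monotone from (0, 0) to (1, 1).

    Thresholds sweep every unique score (no collinear-point dropping, so
    the trapezoidal area equals the Mann-Whitney pair statistic exactly).
    """
    labels = _check_binary(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _skm.roc_curve(labels, np.asarray(probs, dtype=np.float64),
                                 drop_intermediate=False)
    return fpr, tpr


def auc(probs, labels) -> float:
    """Area under the ROC curve (trapezoidal).

    Equals the probability that a random positive outranks a random
    negative, with ties counted as 1/2.
    """
    fpr, tpr = roc_curve(probs, labels)
    return float(_skm.auc(fpr, tpr))


def evaluate_probs(probs, labels, threshold: float = 0.5) -> MetricsReport:
    """Full report (confusion metrics + AUC) for a probability vector."""
    report = compute_metrics(confusion_counts(probs, labels, threshold))
    labels = _check_binary(labels)
    if len(np.unique(labels)) == 2:
        report.auc = auc(probs, labels)
    return report
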