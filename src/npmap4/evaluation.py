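"""Binary classification metrics for origin prediction.

Positive class is "bacterium". Probabilities are thresholded at 0.5 (a
probability of exactly 0.5 counts as positive). Metrics follow the standard
definitions: precision = TP/(TP+FP), recall/TPR = TP/(TP+FN),
TNR = TN/(TN+FP), F1 = harmonic mean of precision and recall, balanced
accuracy = (TPR+TNR)/2, MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
and ROC AUC by trapezoidal integration of the TPR-vs-FPR curve over all
score thresholds. A metric whose denominator vanishes is reported as 0 and
the report carries a degenerate-case flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

POSITIVE = "bacterium"
THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table with "bacterium" as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    roc_auc: float
    f1: float
    balanced_accuracy: float
    mcc: float
    threshold: float = THRESHOLD
    counts: ConfusionCounts | None = None
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {
            "roc_auc": self.roc_auc,
            "f1": self.f1,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "threshold": self.threshold,
            "degenerate": self.degenerate,
        }
        if self.counts is not None:
            d["counts"] = {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            }
        return d


def _binarize_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return (y == POSITIVE).astype(int)
    return y.astype(int)


def confusion(
    labels: Sequence, probabilities: Sequence[float], threshold: float = THRESHOLD
) -> ConfusionCounts:
    """Confusion counts after thresholding positive-class probabilities.

    ``labels`` may be strings ("bacterium"/"fungus") or 0/1 integers.
    A probability equal to the threshold is classified positive.
    """
    y = _binarize_labels(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    pred = (p >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (pred == 1))),
        tn=int(np.sum((y == 0) & (pred == 0))),
        fp=int(np.sum((y == 0) & (pred == 1))),
        fn=int(np.sum((y == 1) & (pred == 0))),
    )


def _safe_div(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def roc_curve(
    labels: Sequence, scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FPR, TPR, thresholds) over all distinct score cutoffs.

    Points are ordered from (0, 0) to (1, 1); both coordinate sequences are
    monotone non-decreasing.
    """
    y = _binarize_labels(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), y.size - 1]
    tps = np.cumsum(y)[distinct].astype(float)
    fps = (distinct + 1) - tps
    n_pos = float(y.sum())
    n_neg = float(y.size - y.sum())
    tpr = np.r_[0.0, tps / n_pos] if n_pos else np.zeros(distinct.size + 1)
    fpr = np.r_[0.0, fps / n_neg] if n_neg else np.zeros(distinct.size + 1)
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def roc_auc(labels: Sequence, scores: Sequence[float]) -> float:
    """Area under the ROC curve by trapezoidal integration; 0 when only one
    class is present (degenerate)."""
    y = _binarize_labels(labels)
    if len(np.unique(y)) < 2:
        return 0.0
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def metric_suite(
    c: ConfusionCounts,
    labels: Sequence | None = None,
    probabilities: Sequence[float] | None = None,
) -> MetricReport:
    """The four reported scores from a confusion table (plus ROC AUC when
    per-molecule scores are supplied)."""
    degenerate: list[str] = []
    precision = _safe_div(c.tp, c.tp + c.fp, "precision", degenerate)
    recall = _safe_div(c.tp, c.tp + c.fn, "recall", degenerate)
    tnr = _safe_div(c.tn, c.tn + c.fp, "tnr", degenerate)
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1", degenerate)
    balanced_accuracy = 0.5 * (recall + tnr)
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    mcc = _safe_div(float(c.tp) * c.tn - float(c.fp) * c.fn, mcc_den, "mcc", degenerate)
    auc = 0.0
    if labels is not None and probabilities is not None:
        auc = roc_auc(labels, probabilities)
        if len(np.unique(_binarize_labels(labels))) < 2:
            degenerate.append("roc_auc")
    else:
        degenerate.append("roc_auc")
    return MetricReport(
        roc_auc=auc,
        f1=f1,
        balanced_accuracy=balanced_accuracy,
        mcc=mcc,
        counts=c,
        degenerate=degenerate,
    )


def evaluate_predictions(
    labels: Sequence, probabilities: Sequence[float], threshold: float = THRESHOLD
) -> MetricReport:
    """Confusion + metric suite in one call."""
    c = confusion(labels, probabilities, threshold)
    report = metric_suite(c, labels, probabilities)
    report.threshold = threshold
    return report


def write_report(report: MetricReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=1) + "\n", encoding="utf-8")
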