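"""Confusion-matrix accounting, precision/recall, PR curves and mAP.

The confusion-matrix convention here puts predicted classes on the ROWS
and actual classes on the COLUMNS (many toolkits transpose this; exports
from other conventions must be transposed on import).  All headline
percentages derive from it: overall accuracy is 100 * trace / total,
precision of class i is the diagonal over its row total, recall of class j
the diagonal over its column total.

Precision-recall curves are swept over every distinct decision-score
threshold, one-vs-rest per class; average precision is the step-wise
(non-interpolated) area sum(precision_k * delta_recall_k), and mAP is the
unweighted mean of the per-class average precisions.  Percentages meant
for comparison against published tables are rounded half-up to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRADES",
    "ConfusionMatrix",
    "PRCurve",
    "PRReport",
    "confusion_matrix",
    "accuracy",
    "per_class_precision_recall",
    "pr_curve",
    "average_precision",
    "mean_average_precision",
    "pr_report",
    "round_half_up",
]

#: Canonical grade order used throughout.
GRADES = ("good", "moderate", "unhealthy")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero toward +inf (102.25 -> 102.3)."""
    scale = 10.0**decimals
    return float(np.floor(x * scale + 0.5) / scale)


@dataclass
class ConfusionMatrix:
    """Counts with rows = predicted class, columns = actual class."""

    counts: np.ndarray  # (k, k) non-negative ints
    classes: tuple

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PRCurve:
    """One-vs-rest precision/recall at every distinct score threshold."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray


@dataclass
class PRReport:
    """Per-class PR curves and average precisions, mAP, overall accuracy."""

    classes: tuple
    curves: dict
    average_precisions: dict
    map_score: float
    accuracy_percent: float
    confusion: ConfusionMatrix | None = None


def confusion_matrix(
    predicted, actual, classes: tuple = GRADES
) -> ConfusionMatrix:
    """counts[i, j] = number of samples predicted class_i with actual class_j."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, a in zip(predicted, actual):
        if p not in index or a not in index:
            raise ValueError(f"unknown label in ({p!r}, {a!r})")
        counts[index[p], index[a]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def accuracy(cm: ConfusionMatrix, decimals: int | None = None) -> float:
    """Overall accuracy in percent: 100 * trace / total.

    ``decimals`` applies half-up rounding (the convention used when
    comparing against one-decimal published tables).
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * np.trace(cm.counts) / total
    return round_half_up(acc, decimals) if decimals is not None else float(acc)


def per_class_precision_recall(cm: ConfusionMatrix) -> dict:
    """Per-class precision (row-wise) and recall (column-wise), in percent.

    A zero denominator yields 0.0 with the class listed under
    ``undefined_precision`` / ``undefined_recall``.
    """
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(row > 0, 100.0 * diag / row, 0.0)
        rec = np.where(col > 0, 100.0 * diag / col, 0.0)
    return {
        "classes": cm.classes,
        "precision_percent": prec,
        "recall_percent": rec,
        "undefined_precision": tuple(
            c for c, r in zip(cm.classes, row) if r == 0
        ),
        "undefined_recall": tuple(
            c for c, r in zip(cm.classes, col) if r == 0
        ),
    }


def pr_curve(scores, binary_labels) -> PRCurve:
    """Precision and recall at every distinct threshold, scores descending.

    ``binary_labels`` marks positives (truthy) one-vs-rest.  Requires at
    least one positive.  Tied scores collapse into a single operating
    point (the threshold admits all of them at once).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(bool)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("need at least one positive label")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    tp = np.cumsum(y[order])
    fp = np.cumsum(~y[order])
    # keep only the last index of each tie group
    distinct = np.nonzero(np.diff(np.append(s, -np.inf)))[0]
    tp, fp, thr = tp[distinct], fp[distinct], s[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return PRCurve(precision=precision, recall=recall, thresholds=thr)


def average_precision(curve: PRCurve) -> float:
    """Step-wise area under the PR curve: sum of precision * delta-recall."""
    recall = np.concatenate([[0.0], curve.recall])
    return float(np.sum(curve.precision * np.diff(recall)))


def mean_average_precision(per_class_ap) -> float:
    """Unweighted mean of per-class average precisions."""
    vals = list(per_class_ap.values()) if isinstance(per_class_ap, dict) else list(per_class_ap)
    if not vals:
        raise ValueError("no average precisions supplied")
    return float(np.mean(vals))


def pr_report(
    actual,
    predicted,
    scores: np.ndarray,
    classes: tuple = GRADES,
) -> PRReport:
    """Full evaluation: confusion matrix, accuracy, per-class PR, mAP.

    ``scores`` holds one column of decision values per class, in
    ``classes`` order.
    """
    actual = np.asarray(actual)
    scores = np.asarray(scores, dtype=float)
    cm = confusion_matrix(predicted, actual, classes)
    curves = {}
    aps = {}
    for j, cls in enumerate(classes):
        curve = pr_curve(scores[:, j], actual == cls)
        curves[cls] = curve
        aps[cls] = average_precision(curve)
    return PRReport(
        classes=tuple(classes),
        curves=curves,
        average_precisions=aps,
        map_score=mean_average_precision(aps),
        accuracy_percent=accuracy(cm),
        confusion=cm,
    )
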