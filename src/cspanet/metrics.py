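"""Evaluation metrics for the three-class ECG task.

Class labels: 0 = healthy control, 1 = concealed accessory pathway (CAP),
2 = atrioventricular nodal reentry tachycardia (AVNRT).

Accuracy is the global trace of the confusion matrix over its total;
sensitivity, specificity and precision are macro-averaged: the unweighted
mean over the three one-vs-rest per-class ratios

    sensitivity_i = TP_i / (TP_i + FN_i)
    specificity_i = TN_i / (TN_i + FP_i)
    precision_i   = TP_i / (TP_i + FP_i)

with TP_i the diagonal cell, FN_i / FP_i the remaining row / column mass
of class i, and TN_i the rest. The loss is the natural-log cross-entropy
over softmax probabilities. ROC curves are one-vs-rest over a class's
probability column with trapezoidal AUC (equal to the tie-corrected
probability-of-correct-ranking statistic).
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InputError

__all__ = [
    "ConfusionMatrix3", "MetricReport", "confusion_from_predictions",
    "macro_metrics", "cross_entropy_loss", "roc_ovr", "macro_ovr_auc",
]

N_CLASSES = 3
PROB_CLAMP = 1e-12


@dataclass
class ConfusionMatrix3:
    """3x3 count matrix; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES, N_CLASSES):
            raise InputError(f"confusion matrix must be 3x3, got {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            if not np.all(c == np.round(c)) or np.any(c < 0):
                raise InputError("confusion matrix entries must be nonnegative integers")
            c = c.astype(np.int64)
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fn(self, i: int) -> int:
        return int(self.counts[i].sum() - self.counts[i, i])

    def fp(self, i: int) -> int:
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def tn(self, i: int) -> int:
        return self.total - self.tp(i) - self.fn(i) - self.fp(i)

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true\\pred", "0", "1", "2"])
            for i in range(N_CLASSES):
                w.writerow([i] + [int(v) for v in self.counts[i]])


@dataclass
class PerClassMetrics:
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    auc: float | None = None


@dataclass
class MetricReport:
    accuracy: float
    macro_sensitivity: float
    macro_specificity: float
    macro_precision: float
    per_class: list
    confusion: ConfusionMatrix3
    macro_auc: float | None = None
    undefined_classes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.counts.tolist()
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def confusion_from_predictions(true_labels, predicted_labels) -> ConfusionMatrix3:
    """Tally counts[i, j] = #(true == i and predicted == j)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise InputError("label sequences must be 1D and of equal length")
    for arr, name in ((t, "true"), (p, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES or
                         not np.all(arr == arr.astype(int))):
            raise InputError(f"{name} labels must be integers in {{0, 1, 2}}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t.astype(int), p.astype(int)), 1)
    return ConfusionMatrix3(counts)


def macro_metrics(cm: ConfusionMatrix3, zero_division: str = "exclude",
                  scores=None, true_labels=None) -> MetricReport:
    """Accuracy plus macro-averaged sensitivity/specificity/precision.

    A class whose denominator is zero (no true or no predicted members)
    yields an undefined ratio; by default it is excluded from the macro
    mean with a warning (``zero_division="zero"`` counts it as 0 instead).
    If ``scores`` (N x 3 probabilities) and ``true_labels`` are given,
    per-class one-vs-rest AUCs and their macro mean are included.
    """
    if cm.total <= 0:
        raise InputError("confusion matrix is empty")
    if zero_division not in ("exclude", "zero"):
        raise InputError(f"unknown zero_division policy {zero_division!r}")
    accuracy = sum(cm.tp(i) for i in range(N_CLASSES)) / cm.total

    per_class = []
    undefined = []
    for i in range(N_CLASSES):
        vals = {}
        for name, num, den in (
            ("sensitivity", cm.tp(i), cm.tp(i) + cm.fn(i)),
            ("specificity", cm.tn(i), cm.tn(i) + cm.fp(i)),
            ("precision", cm.tp(i), cm.tp(i) + cm.fp(i)),
        ):
            if den == 0:
                vals[name] = None
                undefined.append((i, name))
            else:
                vals[name] = num / den
        per_class.append(PerClassMetrics(**vals))
    if undefined:
        warnings.warn(f"undefined per-class ratios excluded from macro mean: {undefined}",
                      RuntimeWarning, stacklevel=2)

    def macro(name):
        vals = [getattr(pc, name) for pc in per_class]
        if zero_division == "zero":
            vals = [0.0 if v is None else v for v in vals]
        else:
            vals = [v for v in vals if v is not None]
        return sum(vals) / len(vals) if vals else float("nan")

    macro_auc = None
    if scores is not None and true_labels is not None:
        aucs = []
        for i in range(N_CLASSES):
            try:
                _, auc = roc_ovr(scores, true_labels, i)
            except InputError:
                auc = None
            per_class[i].auc = auc
            if auc is not None:
                aucs.append(auc)
        macro_auc = sum(aucs) / len(aucs) if aucs else None

    return MetricReport(
        accuracy=accuracy,
        macro_sensitivity=macro("sensitivity"),
        macro_specificity=macro("specificity"),
        macro_precision=macro("precision"),
        per_class=per_class,
        confusion=cm,
        macro_auc=macro_auc,
        undefined_classes=undefined,
    )


def cross_entropy_loss(probabilities, onehot, eps: float = PROB_CLAMP) -> float:
    """Natural-log cross-entropy -sum_i y_i log a_i (batch mean if 2D).

    Zero probability at the true class is clamped at ``eps`` with a
    warning rather than raising.
    """
    a = np.asarray(probabilities, dtype=float)
    y = np.asarray(onehot, dtype=float)
    if a.shape != y.shape or a.shape[-1] != N_CLASSES:
        raise InputError(f"probabilities and onehot must both be (..., 3), got {a.shape}, {y.shape}")
    if np.any(a < 0) or not np.allclose(a.sum(axis=-1), 1.0, atol=1e-6):
        raise InputError("probabilities must be nonnegative and sum to 1")
    if not np.all(np.isin(y.sum(axis=-1), 1.0)) or not np.all(np.isin(y, (0.0, 1.0))):
        raise InputError("onehot must have exactly one 1 per row")
    picked = (a * y).sum(axis=-1)
    if np.any(picked < eps):
        warnings.warn(f"true-class probability below {eps}; clamped", RuntimeWarning,
                      stacklevel=2)
    return float(np.mean(-np.log(np.maximum(picked, eps))))


def roc_ovr(scores, true_labels, class_index: int):
    """One-vs-rest ROC for one class: ((fpr, tpr) points, trapezoidal AUC).

    Points are generated by sweeping thresholds over the class's
    probability column from +inf down through each distinct score, so tied
    scores contribute diagonal segments and the trapezoid rule counts them
    half — identical to the tie-corrected Mann-Whitney ranking statistic.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels)
    if s.ndim != 2 or s.shape[1] != N_CLASSES or s.shape[0] != t.shape[0]:
        raise InputError("scores must be N x 3 aligned with true_labels")
    if class_index not in range(N_CLASSES):
        raise InputError(f"class_index must be in {{0, 1, 2}}, got {class_index}")
    pos = t == class_index
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError(
            f"ROC for class {class_index} is degenerate: "
            f"{n_pos} positives and {n_neg} negatives")
    col = s[:, class_index]
    order = np.argsort(-col, kind="stable")
    col_sorted = col[order]
    pos_sorted = pos[order]
    # cumulative counts at each distinct-threshold boundary
    distinct = np.nonzero(np.diff(col_sorted))[0]
    idx = np.r_[distinct, col_sorted.size - 1]
    tps = np.cumsum(pos_sorted)[idx]
    fps = np.cumsum(~pos_sorted)[idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def macro_ovr_auc(scores, true_labels) -> float:
    """Unweighted mean of the three one-vs-rest AUCs."""
    return sum(roc_ovr(scores, true_labels, i)[1] for i in range(N_CLASSES)) / N_CLASSES


def roc_to_csv(path, scores, true_labels):
    """Write one-vs-rest ROC points for all three classes to one CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "fpr", "tpr"])
        for i in range(N_CLASSES):
            points, _ = roc_ovr(scores, true_labels, i)
            for fpr, tpr in points:
                w.writerow([i, fpr, tpr])
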