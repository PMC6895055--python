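"""Segmentation and classification evaluation.

Implements the evaluation suite used for label-free staining and cell
classification: per-class pixel recall TP/(TP+FN), the boundary-F1 (BF)
contour-matching score at a Euclidean distance tolerance theta (default
0.75% of the image diagonal, strict ``d < theta``), intersection-over-union
TP/(TP+FP+FN), classification accuracy (TP+TN)/total with confusion
matrices, and one-vs-rest ROC curves with trapezoidal AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "PixelCounts",
    "ConfusionMatrix",
    "ROCCurve",
    "pixel_counts",
    "pixel_recall",
    "boundary_pixels",
    "bf_score",
    "iou_score",
    "confusion_and_accuracy",
    "roc_one_vs_rest",
    "DEFAULT_THETA_FRACTION",
]

# boundary tolerance as a fraction of the image diagonal
DEFAULT_THETA_FRACTION = 0.0075


@dataclass(frozen=True)
class PixelCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ConfusionMatrix:
    """Counts with rows = truth, columns = predicted."""

    classes: list
    counts: np.ndarray

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")


@dataclass
class ROCCurve:
    class_name: object
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _check_shapes(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return pred, truth


def _foreground_classes(pred, truth):
    cls = np.union1d(np.unique(pred), np.unique(truth))
    return [int(c) for c in cls if c != 0]


def pixel_counts(pred, truth, cls: int = 1) -> PixelCounts:
    """TP/FP/TN/FN pixel counts for one class."""
    pred, truth = _check_shapes(pred, truth)
    p = pred == cls
    t = truth == cls
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return PixelCounts(tp, fp, tn, fn)


def pixel_recall(pred, truth) -> dict[int, float]:
    """Per-foreground-class recall TP/(TP+FN); 1.0 for a class absent
    from the truth (nothing to recover)."""
    pred, truth = _check_shapes(pred, truth)
    out = {}
    for c in _foreground_classes(pred, truth):
        pc = pixel_counts(pred, truth, c)
        denom = pc.tp + pc.fn
        out[c] = pc.tp / denom if denom else 1.0
    return out


def iou_score(pred, truth) -> dict[int, float]:
    """Per-foreground-class IoU = TP/(TP+FP+FN); 1.0 when the class is
    absent from both masks."""
    pred, truth = _check_shapes(pred, truth)
    out = {}
    for c in _foreground_classes(pred, truth):
        pc = pixel_counts(pred, truth, c)
        denom = pc.tp + pc.fp + pc.fn
        out[c] = pc.tp / denom if denom else 1.0
    return out


def boundary_pixels(mask) -> np.ndarray:
    """Boolean map of contour pixels: foreground pixels with at least one
    background 4-neighbor. Pixels outside the image count as background,
    so foreground touching the border is boundary."""
    fg = np.asarray(mask) > 0
    padded = np.pad(fg, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return fg & ~interior


def _resolve_theta(theta, shape) -> float:
    if theta is None:
        theta = DEFAULT_THETA_FRACTION
    theta = float(theta)
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if theta < 1.0:  # fraction of the image diagonal
        h, w = shape
        theta = theta * math.hypot(h, w)
    return theta


def bf_score(pred, truth, theta: float | None = None) -> float:
    """Boundary-F1 contour matching score of the foreground (mask > 0).

    ``theta`` below 1 is read as a fraction of the image diagonal
    sqrt(h^2 + w^2); otherwise it is a distance in pixels. Precision is the
    fraction of predicted boundary pixels strictly within ``theta`` of the
    truth boundary, recall the converse, and BF = 2PR/(P+R). Conventions:
    both boundaries empty -> 1.0; exactly one empty -> 0.0; P = R = 0 -> 0.0.
    """
    pred, truth = _check_shapes(pred, truth)
    th = _resolve_theta(theta, pred.shape)
    bp = boundary_pixels(pred)
    bg = boundary_pixels(truth)
    np_, ng = int(bp.sum()), int(bg.sum())
    if np_ == 0 and ng == 0:
        return 1.0
    if np_ == 0 or ng == 0:
        return 0.0
    dist_to_g = ndimage.distance_transform_edt(~bg)
    dist_to_p = ndimage.distance_transform_edt(~bp)
    precision = float(np.count_nonzero(dist_to_g[bp] < th)) / np_
    recall = float(np.count_nonzero(dist_to_p[bg] < th)) / ng
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion_and_accuracy(predicted, truth) -> tuple[ConfusionMatrix, float]:
    """Multi-class confusion matrix (rows = truth) and overall accuracy
    trace/total, the micro-average of per-class (TP+TN)/(TP+FP+TN+FN)."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("label sequences must have equal length")
    if not truth:
        raise ValueError("empty label sequences")
    classes = sorted(set(truth))
    unseen = sorted(set(predicted) - set(classes))
    if unseen:
        warnings.warn(f"predicted labels not in truth: {unseen}", stacklevel=2)
        classes = sorted(set(classes) | set(unseen))
    counts = _sk_confusion(truth, predicted, labels=classes)
    cm = ConfusionMatrix(classes=list(classes), counts=counts)
    return cm, cm.accuracy


def roc_one_vs_rest(probabilities, truth, class_names=None) -> list[ROCCurve]:
    """Per-class ROC curves, each class as positive vs the rest.

    ``probabilities`` is (n_items, n_classes) with rows on the simplex;
    ``class_names`` names the columns (defaults to 0..K-1). The curve
    sweeps the distinct scores of the class's probability column; tied
    scores move along the curve together, so the trapezoidal AUC equals
    the midrank Mann-Whitney pair statistic. Classes absent from the
    truth are omitted from the result.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probabilities must be 2-D (items x classes)")
    if np.any(probs < -1e-9) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must be simplices")
    truth = np.asarray(list(truth))
    if truth.shape[0] != probs.shape[0]:
        raise ValueError("truth length must match probabilities")
    if class_names is None:
        class_names = list(range(probs.shape[1]))
    if len(class_names) != probs.shape[1]:
        raise ValueError("class_names length must match probability columns")
    curves = []
    for j, name in enumerate(class_names):
        pos = truth == name
        n_pos = int(pos.sum())
        n_neg = int(pos.size - n_pos)
        if n_pos == 0:
            continue  # curve undefined for a class absent from truth
        scores = probs[:, j]
        order = np.argsort(-scores, kind="stable")
        s_sorted = scores[order]
        pos_sorted = pos[order]
        tp = np.cumsum(pos_sorted)
        fp = np.cumsum(~pos_sorted)
        # keep only the last index of each tied-score block
        distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
        tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
        fpr = np.concatenate([[0.0], fp[distinct] / n_neg]) if n_neg else np.concatenate(
            [[0.0], np.zeros(distinct.size)]
        )
        thresholds = np.concatenate([[np.inf], s_sorted[distinct]])
        auc = float(np.trapezoid(tpr, fpr)) if n_neg else 1.0
        curves.append(ROCCurve(name, fpr, tpr, thresholds, auc))
    return curves
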