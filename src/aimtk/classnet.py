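"""Two-step cell-status classification from TL frames.

Step one proposes cell locations (fixed-size boxes with scores, greedy
non-maximum suppression); step two classifies each fixed-size ROI into
experiment-specific classes (viability / type / maturation analogues).
The proposer is pluggable: a label-free blob proposer on relief gradient
energy, or a trained pixel segmenter. The per-ROI classifier is a small
seeded MLP on normalized, downsampled ROI pixels — the desk-scale
stand-in for a full classification CNN, with the same contract
(probability-simplex outputs, deterministic seeded training, validation
confusion matrix, best-epoch selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, transform
from sklearn.base import BaseEstimator
from sklearn.neural_network import MLPClassifier

from .cellnet import PixelSegmenter, TrainReport
from .core import ROIPatch, as_pixels
from .label_factory import DatasetSplit
from .metrics import confusion_and_accuracy

__all__ = [
    "Detection",
    "ClassProbabilities",
    "ProposerConfig",
    "propose_cells",
    "nms",
    "ROIClassifier",
    "train_classifier",
    "classify_roi",
]


@dataclass(frozen=True)
class Detection:
    """One proposed cell: box center (x, y), box side in px, score in [0,1]."""

    center: tuple[float, float]
    side: int
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass
class ClassProbabilities:
    """Ordered class names with a probability simplex."""

    classes: list[str]
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size != len(self.classes):
            raise ValueError("probability vector must match class names")
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be a simplex")
        self.probabilities = p

    @property
    def predicted(self) -> str:
        # arg-max; ties broken by lowest class index
        return self.classes[int(np.argmax(self.probabilities))]


@dataclass(frozen=True)
class ProposerConfig:
    """method 'blob' (gradient-energy blobs, label-free) or 'segmenter'
    (foreground components of a trained PixelSegmenter)."""

    method: str = "blob"
    box_side: int = 101
    min_area: float = 20.0
    smooth_sigma: float | None = None  # default box_side / 8
    nms_overlap: float = 0.5


def _box_iou(a: Detection, b: Detection) -> float:
    ax0, ay0 = a.center[0] - a.side / 2, a.center[1] - a.side / 2
    bx0, by0 = b.center[0] - b.side / 2, b.center[1] - b.side / 2
    ix = max(0.0, min(ax0 + a.side, bx0 + b.side) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + a.side, by0 + b.side) - max(ay0, by0))
    inter = ix * iy
    union = a.side**2 + b.side**2 - inter
    return inter / union if union > 0 else 0.0


def nms(detections: Sequence[Detection], overlap: float = 0.5) -> list[Detection]:
    """Greedy non-maximum suppression: keep descending-score detections,
    drop any whose box IoU with a kept one is >= ``overlap``."""
    pending = sorted(
        detections, key=lambda d: (-d.score, d.center[0], d.center[1])
    )
    kept: list[Detection] = []
    for d in pending:
        if all(_box_iou(d, k) < overlap for k in kept):
            kept.append(d)
    return kept


def propose_cells(
    tl,
    cfg: ProposerConfig = ProposerConfig(),
    segmenter: Optional[PixelSegmenter] = None,
) -> list[Detection]:
    """Candidate cell detections on one TL frame, NMS-filtered and in
    descending score order. An empty or featureless frame yields []."""
    img = as_pixels(tl).astype(float)
    if min(img.shape) <= cfg.box_side // 2:
        raise ValueError(f"frame {img.shape} too small for box side {cfg.box_side}")
    if cfg.method == "segmenter":
        if segmenter is None:
            raise ValueError("segmenter proposer needs a trained PixelSegmenter")
        proba = segmenter.predict_proba_frame(img, tile=True)
        fg_prob = 1.0 - proba[..., 0]
        fg = np.argmax(proba, axis=-1) > 0
        score_map = fg_prob
    elif cfg.method == "blob":
        sigma = cfg.smooth_sigma if cfg.smooth_sigma is not None else cfg.box_side / 8
        energy = ndimage.gaussian_filter(
            ndimage.gaussian_gradient_magnitude(img, 1.5, mode="reflect"),
            sigma,
            mode="reflect",
        )
        if energy.max() - energy.min() < 1e-12:
            return []
        fg = energy > filters.threshold_otsu(energy)
        score_map = (energy - energy.min()) / (energy.max() - energy.min())
    else:
        raise ValueError(f"unknown proposer method {cfg.method!r}")
    comps = measure.label(fg, connectivity=2)
    cands: list[Detection] = []
    for region in measure.regionprops(comps):
        if region.area < cfg.min_area:
            continue
        cy, cx = region.centroid
        score = float(np.clip(score_map[comps == region.label].mean(), 0.0, 1.0))
        cands.append(Detection(center=(float(cx), float(cy)), side=cfg.box_side, score=score))
    return nms(cands, cfg.nms_overlap)


class ROIClassifier(BaseEstimator):
    """Experiment-specific ROI classifier.

    Each ROI is resized to ``feature_grid`` x ``feature_grid``, patch-
    standardized (zero mean, unit variance) and classified by a seeded MLP.

    Fitted attributes: ``classes_`` (sorted class names), ``mlp_``,
    ``report_`` (with validation confusion matrix in
    ``report_.hyper['confusion']``).
    """

    def __init__(
        self,
        input_side: int = 101,
        feature_grid: int = 16,
        hidden_units: int = 64,
        seed: int = 0,
        epochs: int = 30,
        learning_rate: float = 1e-3,
    ):
        self.input_side = input_side
        self.feature_grid = feature_grid
        self.hidden_units = hidden_units
        self.seed = seed
        self.epochs = epochs
        self.learning_rate = learning_rate

    def _features(self, patch: np.ndarray, resize: bool = False) -> np.ndarray:
        patch = np.asarray(patch, dtype=float)
        if patch.shape != (self.input_side, self.input_side):
            if not resize:
                raise ValueError(
                    f"ROI shape {patch.shape} != classifier input side "
                    f"{self.input_side}; pass resize=True to rescale"
                )
        small = transform.resize(
            patch, (self.feature_grid, self.feature_grid), anti_aliasing=True
        )
        std = small.std()
        if std < 1e-12:
            return np.zeros(small.size)  # constant ROI: degenerate but valid
        return ((small - small.mean()) / std).ravel()

    @staticmethod
    def _patch_of(item) -> np.ndarray:
        return item.image if isinstance(item, ROIPatch) else np.asarray(item)

    def fit(self, patches: Sequence, labels: Optional[Sequence[str]] = None,
            validation: Optional[tuple[Sequence, Sequence[str]]] = None):
        if labels is None:
            labels = [p.label for p in patches]
        labels = np.asarray([str(l) for l in labels])
        classes = sorted(set(labels))
        if len(classes) < 2:
            raise ValueError(f"need >= 2 classes to train, got {classes}")
        self.classes_ = classes
        X = np.stack([self._features(self._patch_of(p)) for p in patches])
        y = np.searchsorted(classes, labels)
        report = TrainReport(
            hyper={
                "epochs": self.epochs,
                "learning_rate": self.learning_rate,
                "optimizer": "adam",
                "seed": self.seed,
            }
        )
        self.report_ = report
        if self.epochs == 0:
            return self
        Xv = yv_names = None
        if validation is not None:
            vp, vl = validation
            Xv = np.stack([self._features(self._patch_of(p)) for p in vp])
            yv_names = np.asarray([str(l) for l in vl])
        mlp = MLPClassifier(
            hidden_layer_sizes=(self.hidden_units,),
            solver="adam",
            learning_rate_init=self.learning_rate,
            random_state=int(self.seed) % (2**31),
            max_iter=1,
        )
        rng = np.random.default_rng(int(self.seed) % (2**31))
        best_acc, best_state, best_epoch = -np.inf, None, -1
        from copy import deepcopy

        for epoch in range(self.epochs):
            idx = rng.permutation(len(y))
            mlp.partial_fit(X[idx], y[idx], classes=np.arange(len(classes)))
            report.losses.append(float(mlp.loss_))
            if Xv is not None:
                pred = [classes[i] for i in mlp.predict(Xv)]
                acc = float(np.mean(np.asarray(pred) == yv_names))
                report.val_accuracies.append(acc)
                if acc > best_acc:
                    best_acc, best_epoch = acc, epoch
                    best_state = (deepcopy(mlp.coefs_), deepcopy(mlp.intercepts_))
        if best_state is not None:
            mlp.coefs_, mlp.intercepts_ = best_state
            report.best_epoch = best_epoch
        else:
            report.best_epoch = self.epochs - 1
        self.mlp_ = mlp
        if Xv is not None:
            pred = [classes[i] for i in mlp.predict(Xv)]
            cm, acc = confusion_and_accuracy(pred, list(yv_names))
            report.hyper["confusion"] = cm
            report.hyper["val_accuracy_best"] = acc
        return self

    def predict_proba(self, patches, resize: bool = False) -> np.ndarray:
        if not hasattr(self, "mlp_"):
            raise RuntimeError("classifier is not trained")
        X = np.stack([self._features(self._patch_of(p), resize=resize) for p in patches])
        return self.mlp_.predict_proba(X)

    def predict(self, patches, resize: bool = False) -> list[str]:
        proba = self.predict_proba(patches, resize=resize)
        return [self.classes_[int(np.argmax(row))] for row in proba]


def train_classifier(
    split: DatasetSplit,
    seed: int = 0,
    **hyper,
) -> tuple[ROIClassifier, TrainReport]:
    """Train a ROI classifier on a sample-level split; returns
    ``(model, report)`` with the validation confusion matrix in the
    report. Rejects single-class datasets."""
    split.assert_no_leakage()
    if not split.train:
        raise ValueError("empty training split")
    side = split.train[0].side
    clf = ROIClassifier(input_side=side, seed=seed, **hyper)
    val = None
    if split.validation:
        val = (split.validation, [p.label for p in split.validation])
    clf.fit(split.train, validation=val)
    return clf, clf.report_


def classify_roi(model: ROIClassifier, roi, resize: bool = False) -> ClassProbabilities:
    """Class probabilities for a single ROI (no silent resizing unless
    ``resize`` is set)."""
    proba = model.predict_proba([roi], resize=resize)[0]
    return ClassProbabilities(classes=list(model.classes_), probabilities=proba)
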