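"""Pixel-wise in-silico staining: TL frame -> label map.

The segmenter ("CellNet" role) maps transmitted-light images to per-pixel
structure classes, trained on label masks derived from fluorescence
channels. The desk-scale backend is a fixed multiscale convolutional
filter bank (Gaussian smoothing, gradient magnitude and Laplacian at
``depth + 1`` dyadic scales) feeding a small seeded multilayer perceptron
read-out — a configurable, CPU-trainable stand-in for a full
encoder-decoder, honoring the same contract: seeded deterministic
initialization and training, per-epoch loss / validation pixel accuracy
reporting with best-epoch selection, probability-simplex outputs, and
overlap-blended tiling for frames larger than the training size.
"""

from __future__ import annotations

import hashlib
from copy import deepcopy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.neural_network import MLPClassifier

from .core import as_pixels

__all__ = [
    "SegmenterConfig",
    "TrainReport",
    "PixelSegmenter",
    "build_segmenter",
    "train_segmenter",
    "segment",
]


@dataclass(frozen=True)
class SegmenterConfig:
    """input_size must be divisible by 2**depth (the coarsest feature
    scale); base_channels is the read-out hidden width; class_weights
    'balanced' resamples training pixels to equal class frequency."""

    input_size: int = 64
    n_classes: int = 2
    depth: int = 2
    base_channels: int = 64
    class_weights: str | None = "balanced"
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )


@dataclass
class TrainReport:
    """Per-epoch training log: loss, validation accuracy, best epoch."""

    losses: list[float] = field(default_factory=list)
    val_accuracies: list[float] = field(default_factory=list)
    best_epoch: int = -1
    final_checksum: str = ""
    hyper: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.losses)


def _feature_stack(img: np.ndarray, depth: int) -> np.ndarray:
    """Per-pixel convolutional features at scales 1, 2, ..., 2**depth px:
    smoothed intensity, gradient magnitude (raw and re-smoothed at twice
    the scale), Laplacian and local standard deviation, plus the raw
    intensity itself."""
    img = np.asarray(img, dtype=float)
    feats = [img]
    for s in range(depth + 1):
        sigma = float(2**s)
        g = ndimage.gaussian_filter(img, sigma, mode="reflect")
        gm = ndimage.gaussian_gradient_magnitude(img, sigma, mode="reflect")
        feats.append(g)
        feats.append(gm)
        feats.append(ndimage.gaussian_laplace(img, sigma, mode="reflect"))
        feats.append(ndimage.gaussian_filter(gm, 2 * sigma, mode="reflect"))
        local_var = ndimage.gaussian_filter(img * img, sigma, mode="reflect") - g * g
        feats.append(np.sqrt(np.clip(local_var, 0.0, None)))
    return np.stack(feats, axis=-1)


class PixelSegmenter(BaseEstimator):
    """Trainable pixel classifier for in-silico staining.

    Parameters mirror :class:`SegmenterConfig` plus training hyper-
    parameters. Fitted attributes: ``mlp_`` (the read-out), ``report_``
    (:class:`TrainReport`), ``classes_``.
    """

    def __init__(
        self,
        input_size: int = 64,
        n_classes: int = 2,
        depth: int = 2,
        base_channels: int = 64,
        class_weights: str | None = "balanced",
        seed: int = 0,
        epochs: int = 30,
        learning_rate: float = 1e-3,
        pixels_per_class: int = 20000,
    ):
        self.input_size = input_size
        self.n_classes = n_classes
        self.depth = depth
        self.base_channels = base_channels
        self.class_weights = class_weights
        self.seed = seed
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.pixels_per_class = pixels_per_class

    # -- configuration --------------------------------------------------
    @property
    def config(self) -> SegmenterConfig:
        return SegmenterConfig(
            self.input_size,
            self.n_classes,
            self.depth,
            self.base_channels,
            self.class_weights,
            self.seed,
        )

    def _n_features(self) -> int:
        return 1 + 5 * (self.depth + 1)

    def _build_mlp(self) -> MLPClassifier:
        mlp = MLPClassifier(
            hidden_layer_sizes=(self.base_channels,),
            solver="adam",
            learning_rate_init=self.learning_rate,
            random_state=int(self.seed) % (2**31),
            max_iter=1,
            warm_start=False,
        )
        # force seeded weight initialization with a constant dummy batch
        x0 = np.zeros((self.n_classes, self._n_features()))
        mlp.partial_fit(x0, np.arange(self.n_classes), classes=np.arange(self.n_classes))
        return mlp

    def parameter_checksum(self) -> str:
        """SHA-256 over the read-out weights (seeded init if unfitted)."""
        mlp = getattr(self, "mlp_", None)
        if mlp is None:
            mlp = self._build_mlp()
        h = hashlib.sha256()
        for arr in [*mlp.coefs_, *mlp.intercepts_]:
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    # -- training --------------------------------------------------------
    def _check_pair(self, tl, mask):
        tl = as_pixels(tl).astype(float)
        mask = np.asarray(mask)
        if tl.shape != (self.input_size, self.input_size):
            raise ValueError(
                f"training patch shape {tl.shape} != input_size {self.input_size}"
            )
        if mask.shape != tl.shape:
            raise ValueError("mask shape must match its TL patch")
        if mask.min() < 0 or mask.max() >= self.n_classes:
            raise ValueError(
                f"mask class ids must be in [0, {self.n_classes}); "
                f"found range [{mask.min()}, {mask.max()}]"
            )
        return tl, mask

    def fit(self, pairs: Sequence[tuple], validation: Optional[Sequence[tuple]] = None):
        """Train on (TL patch, label mask) pairs.

        ``validation`` pairs drive per-epoch pixel accuracy and best-epoch
        selection (falls back to the final epoch when absent).
        """
        self.config  # validate
        pairs = [self._check_pair(t, m) for t, m in pairs]
        report = TrainReport(
            hyper={
                "epochs": self.epochs,
                "learning_rate": self.learning_rate,
                "pixels_per_class": self.pixels_per_class,
                "optimizer": "adam",
                "seed": self.seed,
            }
        )
        self.classes_ = np.arange(self.n_classes)
        self.report_ = report
        if self.epochs == 0 or not pairs:
            return self  # model unchanged, report empty
        X = np.concatenate([_feature_stack(t, self.depth).reshape(-1, self._n_features())
                            for t, _ in pairs])
        y = np.concatenate([m.ravel() for _, m in pairs])
        Xv = yv = None
        if validation:
            vpairs = [self._check_pair(t, m) for t, m in validation]
            Xv = np.concatenate(
                [_feature_stack(t, self.depth).reshape(-1, self._n_features()) for t, _ in vpairs]
            )
            yv = np.concatenate([m.ravel() for _, m in vpairs])
        mlp = self._build_mlp()
        rng = np.random.default_rng(int(self.seed) % (2**31))
        by_class = [np.flatnonzero(y == c) for c in range(self.n_classes)]
        best_acc, best_state, best_epoch = -np.inf, None, -1
        for epoch in range(self.epochs):
            if self.class_weights == "balanced":
                # equal pixel counts per class (inverse-frequency weighting
                # by resampling); capped by the rarest class
                n_per = min(
                    self.pixels_per_class, min(ix.size for ix in by_class if ix.size)
                )
                idx = np.concatenate(
                    [rng.choice(ix, size=n_per, replace=False) for ix in by_class if ix.size]
                )
            else:
                n = min(y.size, self.pixels_per_class * self.n_classes)
                idx = rng.choice(y.size, size=n, replace=False)
            rng.shuffle(idx)
            mlp.partial_fit(X[idx], y[idx], classes=self.classes_)
            report.losses.append(float(mlp.loss_))
            if Xv is not None:
                acc = float(np.mean(mlp.predict(Xv) == yv))
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
        report.final_checksum = self.parameter_checksum()
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba_frame(self, tl, tile: bool = False) -> np.ndarray:
        """Per-pixel class probabilities, shape (h, w, n_classes)."""
        if not hasattr(self, "mlp_"):
            raise RuntimeError("segmenter is not trained")
        img = as_pixels(tl).astype(float)
        ts = self.input_size
        h, w = img.shape
        if (h, w) == (ts, ts):
            return self._proba_tile(img)
        if not tile:
            raise ValueError(
                f"frame shape {img.shape} != input_size {ts}; pass tile=True to "
                "process by overlapped tiling"
            )
        if h < ts or w < ts:
            pt, pl = max(0, ts - h), max(0, ts - w)
            padded = np.pad(img, ((0, pt), (0, pl)), mode="reflect")
            return self.predict_proba_frame(padded, tile=True)[:h, :w]
        stride = ts // 2
        win1 = np.bartlett(ts + 2)[1:-1]
        weight = np.outer(win1, win1) + 1e-6
        acc = np.zeros((h, w, self.n_classes))
        wsum = np.zeros((h, w))
        rows = sorted({*range(0, h - ts + 1, stride), h - ts})
        cols = sorted({*range(0, w - ts + 1, stride), w - ts})
        for r in rows:
            for c in cols:
                p = self._proba_tile(img[r : r + ts, c : c + ts])
                acc[r : r + ts, c : c + ts] += p * weight[..., None]
                wsum[r : r + ts, c : c + ts] += weight
        acc /= wsum[..., None]
        acc /= acc.sum(axis=-1, keepdims=True)
        return acc

    def _proba_tile(self, img: np.ndarray) -> np.ndarray:
        feats = _feature_stack(img, self.depth).reshape(-1, self._n_features())
        proba = self.mlp_.predict_proba(feats)
        return proba.reshape(*img.shape, self.n_classes)

    def predict(self, tl, tile: bool = False) -> np.ndarray:
        """Arg-max label mask for one frame."""
        return np.argmax(self.predict_proba_frame(tl, tile=tile), axis=-1).astype(np.int32)


def build_segmenter(cfg: SegmenterConfig, **hyper) -> PixelSegmenter:
    """Instantiate a seeded, unfitted segmenter from a config."""
    return PixelSegmenter(
        input_size=cfg.input_size,
        n_classes=cfg.n_classes,
        depth=cfg.depth,
        base_channels=cfg.base_channels,
        class_weights=cfg.class_weights,
        seed=cfg.seed,
        **hyper,
    )


def train_segmenter(
    model: PixelSegmenter,
    train_pairs: Sequence[tuple],
    val_pairs: Optional[Sequence[tuple]] = None,
    **hyper,
) -> tuple[PixelSegmenter, TrainReport]:
    """Train and return ``(model, report)``; ``hyper`` overrides the
    model's epochs / learning_rate / pixels_per_class."""
    if hyper:
        model.set_params(**hyper)
    model.fit(train_pairs, validation=val_pairs)
    return model, model.report_


def segment(model: PixelSegmenter, tl, tile: bool = False):
    """Segment one frame: ``(label mask, per-pixel probabilities)``."""
    proba = model.predict_proba_frame(tl, tile=tile)
    return np.argmax(proba, axis=-1).astype(np.int32), proba
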