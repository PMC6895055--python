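"""Training-label generation from fluorescence images.

Fluorescence channels are turned into integer label masks by 1-D K-means
on pixel intensity with deterministic quantile seeding, followed by a
size-constrained object filter (the "hierarchical" step): connected
foreground components whose area falls outside the configured bounds are
dropped. Labelled ROI datasets are then assembled with sample-level
train/validation/test splits so that no biological replicate leaks across
splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.base import BaseEstimator

from .core import ROIPatch, as_pixels, crop_patch, round_half_away

__all__ = [
    "HKParams",
    "HKMeansSegmenter",
    "DatasetSplit",
    "hkmeans_segment",
    "extract_rois",
    "assemble_dataset",
]


@dataclass(frozen=True)
class HKParams:
    """n_classes: intensity classes K (2..16); object_area_bounds: inclusive
    (min, max) component area in px^2 kept as foreground."""

    n_classes: int = 2
    object_area_bounds: tuple[float, float] = (1.0, np.inf)

    def __post_init__(self):
        if not (2 <= self.n_classes <= 16):
            raise ValueError("n_classes must be in [2, 16]")
        lo, hi = self.object_area_bounds
        if not lo < hi:
            raise ValueError("object_area_bounds must satisfy min < max")


class HKMeansSegmenter(BaseEstimator):
    """Intensity K-means segmenter with size-filtered objects.

    A 1-D K-means on pixel intensities, seeded at the (i + 0.5)/K quantiles
    of the distinct intensity values and iterated to convergence (tol 1e-6
    on centroid movement, max 100 iterations). Classes are ordered by ascending centroid; class 0
    (darkest) is background and every other class is foreground. Connected
    foreground components with area outside ``area_bounds`` are removed.

    Parameters
    ----------
    n_classes : int
        Number of intensity classes K, 2..16.
    area_bounds : (float, float)
        Inclusive component-area bounds in pixels.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k,)
        Ascending intensity centroids after fitting (k <= n_classes if the
        image had fewer distinct values).
    n_iter_ : int
        Lloyd iterations run.
    """

    def __init__(self, n_classes: int = 2, area_bounds: tuple[float, float] = (1.0, np.inf)):
        self.n_classes = n_classes
        self.area_bounds = area_bounds

    def fit(self, image, y=None):
        HKParams(self.n_classes, tuple(self.area_bounds))  # validate
        values = as_pixels(image).astype(float).ravel()
        distinct = np.unique(values)
        k = self.n_classes
        if distinct.size < k:
            warnings.warn(
                f"image has {distinct.size} distinct intensities < K={k}; "
                f"collapsing to {distinct.size} classes",
                stacklevel=2,
            )
            k = max(1, distinct.size)
        # seed at quantiles of the distinct values: robust to sparse
        # foreground, where pixel-mass quantiles would coincide on the
        # background level and collapse the seeding
        centers = np.unique(np.quantile(distinct, (np.arange(k) + 0.5) / k))
        n_iter = 0
        for n_iter in range(1, 101):
            if centers.size == 1:
                break
            edges = (centers[:-1] + centers[1:]) / 2.0
            assign = np.searchsorted(edges, values)
            new = centers.copy()
            sums = np.bincount(assign, weights=values, minlength=centers.size)
            cnts = np.bincount(assign, minlength=centers.size)
            nonempty = cnts > 0
            new[nonempty] = sums[nonempty] / cnts[nonempty]
            new.sort()
            if np.max(np.abs(new - centers)) < 1e-6:
                centers = new
                break
            centers = new
        self.cluster_centers_ = centers
        self.n_iter_ = n_iter
        return self

    def predict(self, image) -> np.ndarray:
        pixels = as_pixels(image).astype(float)
        centers = self.cluster_centers_
        if centers.size == 1:
            return np.zeros(pixels.shape, dtype=np.int32)
        edges = (centers[:-1] + centers[1:]) / 2.0
        mask = np.searchsorted(edges, pixels.ravel()).reshape(pixels.shape).astype(np.int32)
        return self._size_filter(mask)

    def fit_predict(self, image, y=None) -> np.ndarray:
        return self.fit(image).predict(image)

    def _size_filter(self, mask: np.ndarray) -> np.ndarray:
        lo, hi = self.area_bounds
        fg = mask > 0
        if not fg.any():
            return mask
        comps = measure.label(fg, connectivity=2)
        areas = np.bincount(comps.ravel())
        bad = np.zeros(areas.size, dtype=bool)
        bad[1:] = (areas[1:] < lo) | (areas[1:] > hi)
        mask = mask.copy()
        mask[bad[comps]] = 0
        return mask


def hkmeans_segment(fl, params: HKParams | None = None) -> np.ndarray:
    """Segment a fluorescence frame into an integer label mask.

    Thin functional wrapper over :class:`HKMeansSegmenter`.
    """
    params = params or HKParams()
    seg = HKMeansSegmenter(params.n_classes, params.object_area_bounds)
    return seg.fit_predict(fl)


def extract_rois(
    frames,
    mask: np.ndarray,
    roi_side: int = 101,
    sample_id: str = "",
    frame_index: int = 0,
) -> list[ROIPatch]:
    """One ROI per foreground connected component of ``mask``.

    ``frames`` is a mapping of channel name to image (a single array is
    taken as channel ``"tl"``). Each ROI is centered at the component
    centroid rounded half away from zero; crops falling outside the image
    are reflect-padded and flagged.
    """
    if roi_side % 2 == 0:
        raise ValueError(f"roi_side must be odd, got {roi_side}")
    if not isinstance(frames, dict):
        frames = {"tl": frames}
    frames = {k: as_pixels(v) for k, v in frames.items()}
    mask = np.asarray(mask)
    for name, img in frames.items():
        if img.shape != mask.shape:
            raise ValueError(f"frame {name!r} shape {img.shape} != mask shape {mask.shape}")
    comps = measure.label(mask > 0, connectivity=2)
    rois: list[ROIPatch] = []
    for rc in ndimage.center_of_mass(mask > 0, comps, range(1, comps.max() + 1)):
        cy, cx = rc
        center = (float(round_half_away(cx)), float(round_half_away(cy)))
        images = {}
        padded = False
        for name, img in frames.items():
            patch, pad = crop_patch(img, center, roi_side)
            images[name] = patch
            padded = padded or pad
        rois.append(
            ROIPatch(
                images=images,
                center=center,
                side=roi_side,
                sample_id=sample_id,
                frame_index=frame_index,
                padded=padded,
            )
        )
    return rois


@dataclass
class DatasetSplit:
    """Sample-level disjoint train/validation/test ROI sets."""

    train: list[ROIPatch] = field(default_factory=list)
    validation: list[ROIPatch] = field(default_factory=list)
    test: list[ROIPatch] = field(default_factory=list)
    sample_sets: dict[str, set[str]] = field(default_factory=dict)

    def assert_no_leakage(self) -> None:
        sets = list(self.sample_sets.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise AssertionError(f"sample leakage across splits: {sorted(overlap)}")
        for name, rois in (
            ("train", self.train),
            ("validation", self.validation),
            ("test", self.test),
        ):
            allowed = self.sample_sets.get(name, set())
            for r in rois:
                if r.sample_id not in allowed:
                    raise AssertionError(
                        f"ROI from sample {r.sample_id!r} in split {name!r} "
                        f"whose samples are {sorted(allowed)}"
                    )

    def counts(self) -> dict[str, dict]:
        out = {}
        for name, rois in (
            ("train", self.train),
            ("validation", self.validation),
            ("test", self.test),
        ):
            per_class: dict = {}
            for r in rois:
                per_class[r.label] = per_class.get(r.label, 0) + 1
            out[name] = {"total": len(rois), "per_class": per_class}
        return out


def assemble_dataset(
    rois: Sequence[ROIPatch],
    split_rule: Sequence[int] = (2, 1),
    seed: int | None = None,
) -> DatasetSplit:
    """Split ROIs into train/validation(/test) by sample, never by ROI.

    ``split_rule`` gives the number of samples per split, e.g. ``(2, 1)``
    for 2 training and 1 validation sample, ``(4, 1, 1)`` adding a test
    split. Samples are taken in sorted order (shuffled first when ``seed``
    is given), so the split is deterministic.
    """
    rule = [int(v) for v in split_rule]
    if not (2 <= len(rule) <= 3) or any(v < 1 for v in rule):
        raise ValueError("split_rule must be 2 or 3 positive sample counts")
    by_sample: dict[str, list[ROIPatch]] = {}
    for r in rois:
        by_sample.setdefault(r.sample_id, []).append(r)
    sample_ids = sorted(by_sample)
    if len(sample_ids) < sum(rule):
        raise ValueError(
            f"split rule {tuple(rule)} needs {sum(rule)} samples, got {len(sample_ids)} "
            f"({sample_ids})"
        )
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(sample_ids))
        sample_ids = [sample_ids[i] for i in order]
    names = ["train", "validation", "test"][: len(rule)]
    split = DatasetSplit()
    start = 0
    for name, count in zip(names, rule):
        chosen = set(sample_ids[start : start + count])
        start += count
        split.sample_sets[name] = chosen
        bucket = getattr(split, name)
        for sid in sorted(chosen):
            bucket.extend(by_sample[sid])
    split.assert_no_leakage()
    return split
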