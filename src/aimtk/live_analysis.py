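"""Label-free multimodal trajectory analysis.

For every tracked cell, ROIs centered on the track coordinates are
extracted from the TL stack and analyzed by the trained pixel segmenter
(nucleus area over time) and by one or more ROI classifiers (class
probabilities over time). Motility is summarized by cumulative
displacement and the time-averaged mean squared displacement (MSD), and
state changes (death, maturation analogues) are detected as the first
frame where a designated class probability stays above a threshold for a
persistence window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .cellnet import PixelSegmenter
from .classnet import ROIClassifier
from .core import Track, as_pixels, crop_patch

__all__ = [
    "TrajectoryReport",
    "analyze_trajectory",
    "cumulative_displacement",
    "msd",
    "detect_state_change",
    "ensemble_msd",
]


@dataclass
class TrajectoryReport:
    """Per-track time series produced by :func:`analyze_trajectory`."""

    track_id: int
    frames: np.ndarray  # frame indices
    times_min: np.ndarray  # minutes from track birth
    positions: np.ndarray  # (n, 2) as (x, y)
    nucleus_area_px: np.ndarray  # 0 where no nucleus was found
    nucleus_area_um2: np.ndarray
    nucleus_present: np.ndarray  # bool
    class_probabilities: dict[str, pd.DataFrame]  # head -> frames x classes
    cumulative_displacement_px: np.ndarray
    msd_px2: np.ndarray  # index = lag (MSD[0] = 0)
    events: list[tuple[str, int]] = field(default_factory=list)  # (head:class, frame)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per track-frame."""
        df = pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": self.frames,
                "time_min": self.times_min,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "nucleus_area_px": self.nucleus_area_px,
                "nucleus_area_um2": self.nucleus_area_um2,
                "nucleus_present": self.nucleus_present,
                "cumulative_displacement_px": self.cumulative_displacement_px,
            }
        )
        for head, probs in self.class_probabilities.items():
            for cls in probs.columns:
                df[f"p_{head}_{cls}"] = probs[cls].to_numpy()
        return df


def cumulative_displacement(track: Track | np.ndarray) -> np.ndarray:
    """Partial sums of Euclidean step lengths; first value 0."""
    xy = track.xy if isinstance(track, Track) else np.asarray(track, dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 positions")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def msd(track: Track | np.ndarray, max_lag: Optional[int] = None) -> np.ndarray:
    """Time-averaged mean squared displacement.

    ``out[tau] = mean_t |r(t + tau) - r(t)|^2`` for lags 0..max_lag
    (``out[0] = 0``), in px^2. ``max_lag`` defaults to length - 1 and must
    be smaller than the track length.
    """
    xy = track.xy if isinstance(track, Track) else np.asarray(track, dtype=float)
    n = xy.shape[0]
    if max_lag is None:
        max_lag = n - 1
    if not (1 <= max_lag < n):
        raise ValueError(f"max_lag must be in [1, {n - 1}], got {max_lag}")
    out = np.zeros(max_lag + 1)
    for tau in range(1, max_lag + 1):
        d = xy[tau:] - xy[:-tau]
        out[tau] = float(np.mean(np.sum(d * d, axis=1)))
    return out


def ensemble_msd(tracks: Sequence[Track | np.ndarray], max_lag: int) -> np.ndarray:
    """Mean of per-track time-averaged MSD curves."""
    return np.mean([msd(t, max_lag) for t in tracks], axis=0)


def detect_state_change(
    prob_series: Sequence[float], threshold: float = 0.5, persistence: int = 3
) -> Optional[int]:
    """First frame where the probability reaches ``threshold`` and stays
    there for ``persistence`` consecutive frames; None if never."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    p = np.asarray(prob_series, dtype=float)
    above = p >= threshold
    for start in range(p.size - persistence + 1):
        if above[start : start + persistence].all():
            return start
    return None


def _nucleus_area(seg_mask: np.ndarray) -> tuple[float, bool]:
    """Area of the foreground component whose centroid is nearest the
    patch center; (0, False) when the patch has no foreground."""
    fg = seg_mask > 0
    if not fg.any():
        return 0.0, False
    comps = measure.label(fg, connectivity=2)
    h, w = seg_mask.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    best_area, best_dist = 0.0, np.inf
    for region in measure.regionprops(comps):
        d = float(np.linalg.norm(np.asarray(region.centroid) - center))
        if d < best_dist:
            best_dist, best_area = d, float(region.area)
    return best_area, True


def analyze_trajectory(
    track: Track,
    tl_stack,
    segmenter: Optional[PixelSegmenter] = None,
    classifiers: Optional[Mapping[str, ROIClassifier]] = None,
    roi_side: int = 101,
    frame_interval_min: float = 5.0,
    pixel_size_um: float = 1.0,
    event_rules: Optional[Mapping[str, tuple[str, float, int]]] = None,
) -> TrajectoryReport:
    """Analyze one track against its TL stack.

    Per frame, an odd-sided ROI is cropped at the track center
    (reflect-padded at borders); the segmenter measures the nucleus
    nearest the ROI center; each classifier head yields a probability
    vector. ``event_rules`` maps a head name to ``(class_name, threshold,
    persistence)``; detected events are reported as ``(head:class,
    frame)`` with the frame given in track frame indices.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if roi_side % 2 == 0:
        raise ValueError("roi_side must be odd")
    stack = np.asarray(as_pixels(tl_stack))
    n_frames, h, w = stack.shape
    frames = np.asarray(track.frames)
    xy = track.xy
    if frames.max() >= n_frames:
        raise ValueError("track frame index outside stack")
    if (xy[:, 0].min() < 0 or xy[:, 0].max() > w - 1
            or xy[:, 1].min() < 0 or xy[:, 1].max() > h - 1):
        raise ValueError("track positions outside stack bounds")
    classifiers = dict(classifiers or {})
    areas = np.zeros(len(track))
    present = np.zeros(len(track), dtype=bool)
    prob_rows: dict[str, list[np.ndarray]] = {k: [] for k in classifiers}
    for i, (f, (x, y)) in enumerate(zip(frames, xy)):
        roi, _ = crop_patch(stack[f], (x, y), roi_side)
        if segmenter is not None:
            mask = segmenter.predict(roi, tile=True)
            areas[i], present[i] = _nucleus_area(mask)
        for head, clf in classifiers.items():
            prob_rows[head].append(clf.predict_proba([roi], resize=True)[0])
    class_probs = {
        head: pd.DataFrame(np.vstack(rows), index=frames, columns=classifiers[head].classes_)
        for head, rows in prob_rows.items()
    }
    events: list[tuple[str, int]] = []
    for head, (cls_name, thr, pers) in (event_rules or {}).items():
        series = class_probs[head][cls_name].to_numpy()
        hit = detect_state_change(series, threshold=thr, persistence=pers)
        if hit is not None:
            events.append((f"{head}:{cls_name}", int(frames[hit])))
    return TrajectoryReport(
        track_id=track.track_id,
        frames=frames,
        times_min=(frames - frames[0]) * float(frame_interval_min),
        positions=xy,
        nucleus_area_px=areas,
        nucleus_area_um2=areas * pixel_size_um**2,
        nucleus_present=present,
        class_probabilities=class_probs,
        cumulative_displacement_px=cumulative_displacement(track) if len(track) >= 2
        else np.zeros(1),
        msd_px2=msd(track) if len(track) >= 2 else np.zeros(1),
        events=events,
    )
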