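"""Live-cell tracking by a correlation-filter / intensity-histogram ensemble.

One tracked cell is represented by a cosine-windowed appearance template
and a foreground/background intensity-histogram pair. Each step evaluates
two response maps over a search window centered on the previous position:
the normalized cross-correlation of the template (computed in the
frequency domain) and the box-integrated per-pixel foreground probability
obtained from the two histograms by Bayes' rule. Both maps are rescaled to
[0, 1] and fused as ``(1 - alpha) * corr + alpha * hist``; the new center
is the arg-max of the fused response. Template and histograms are updated
by exponential moving averages. Multi-object tracking seeds tracks from a
detector, re-associates detections to active tracks every few frames by
gated nearest-neighbor matching, and terminates tracks whose response
stays below a floor.

Tracking is translation-only (no scale or rotation adaptation) and fully
deterministic: same frames and parameters give identical tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .classnet import Detection
from .core import Track, as_pixels, crop_patch

__all__ = [
    "TrackParams",
    "TrackerState",
    "init_track",
    "step_track",
    "track_video",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TrackParams:
    """Ensemble weights and update rates.

    alpha mixes the two responses (0 = pure correlation, 1 = pure
    histogram); eta_cf / eta_hist are the template / histogram learning
    rates; the search window is ``search_scale`` times the box side.
    """

    n_bins: int = 32
    alpha: float = 0.3
    eta_cf: float = 0.01
    eta_hist: float = 0.04
    search_scale: float = 2.0
    box_side: Optional[int] = None  # override detection box side

    def __post_init__(self):
        for name in ("alpha", "eta_cf", "eta_hist"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.search_scale <= 1.0:
            raise ValueError("search_scale must be > 1")


@dataclass
class TrackerState:
    template: np.ndarray  # cosine-windowed appearance, (side, side)
    hist_fg: np.ndarray  # (n_bins,), sums to 1
    hist_bg: np.ndarray
    center: tuple[float, float]  # (x, y)
    side: int
    params: TrackParams
    lost: bool = False


def _to_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / float(np.iinfo(img.dtype).max)
    return img.astype(float)


def _window(side: int) -> np.ndarray:
    w = np.hanning(side + 2)[1:-1]
    return np.outer(w, w)


def _histogram(values: np.ndarray, n_bins: int) -> np.ndarray:
    h, _ = np.histogram(np.clip(values, 0.0, 1.0), bins=n_bins, range=(0.0, 1.0))
    h = h.astype(float)
    s = h.sum()
    return h / s if s > 0 else np.full(n_bins, 1.0 / n_bins)


def _search_side(side: int, scale: float) -> int:
    s = int(round(side * scale))
    return s + 1 - s % 2  # odd, so the window has a center pixel


def init_track(frame, center: tuple[float, float], side: int, params: TrackParams = TrackParams()) -> TrackerState:
    """Initialize tracker state from one frame and a box (center, side).

    The box center must lie inside the frame; crops that cross the border
    are reflect-padded. Foreground histogram comes from the box interior,
    background from the surrounding search-window ring.
    """
    img = _to_float(as_pixels(frame))
    h, w = img.shape
    x, y = center
    if side % 2 == 0:
        raise ValueError(f"box side must be odd, got {side}")
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise ValueError(f"box center {center} outside frame {img.shape}")
    patch, _ = crop_patch(img, center, side)
    template = patch * _window(side)
    ss = _search_side(side, params.search_scale)
    surround, _ = crop_patch(img, center, ss)
    ring = np.ones((ss, ss), dtype=bool)
    off = (ss - side) // 2
    ring[off : off + side, off : off + side] = False
    hist_fg = _histogram(patch.ravel(), params.n_bins)
    hist_bg = _histogram(surround[ring], params.n_bins)
    return TrackerState(template, hist_fg, hist_bg, (float(x), float(y)), side, params)


def correlation_response(state: TrackerState, search: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of the template over the search window
    (FFT-based); index (i, j) is the response with the template centered
    at that pixel."""
    return match_template(search, state.template, pad_input=True, mode="reflect")


def histogram_response(state: TrackerState, search: np.ndarray) -> np.ndarray:
    """Box-integrated per-pixel foreground probability from the
    foreground/background histograms (Bayes with equal priors)."""
    nb = state.params.n_bins
    bins = np.clip((np.clip(search, 0, 1) * nb).astype(int), 0, nb - 1)
    p_fg = (state.hist_fg[bins] + _EPS) / (state.hist_fg[bins] + state.hist_bg[bins] + 2 * _EPS)
    return ndimage.uniform_filter(p_fg, size=state.side, mode="constant")


def _unit_scale(r: np.ndarray) -> np.ndarray:
    lo, hi = float(r.min()), float(r.max())
    if hi - lo < _EPS:
        return np.full_like(r, 0.5)
    return (r - lo) / (hi - lo)


def step_track(state: TrackerState, frame) -> tuple[tuple[float, float], float, TrackerState]:
    """Advance one frame: ``(new_center, response_score, new_state)``.

    The fused response is ``(1 - alpha) * corr + alpha * hist`` after each
    map is min-max rescaled to [0, 1]; arg-max ties resolve to the first
    (row-major) position. A previous center outside the frame marks the
    track lost without stepping.
    """
    img = _to_float(as_pixels(frame))
    h, w = img.shape
    x0, y0 = state.center
    if not (0 <= x0 <= w - 1 and 0 <= y0 <= h - 1):
        return state.center, 0.0, replace(state, lost=True)
    p = state.params
    ss = _search_side(state.side, p.search_scale)
    cx, cy = int(round(x0)), int(round(y0))
    search, _ = crop_patch(img, (cx, cy), ss)
    corr_raw = correlation_response(state, search)
    hist_raw = histogram_response(state, search)
    fused = (1.0 - p.alpha) * _unit_scale(corr_raw) + p.alpha * _unit_scale(hist_raw)
    iy, ix = np.unravel_index(int(np.argmax(fused)), fused.shape)
    half = ss // 2
    nx, ny = cx + (ix - half), cy + (iy - half)
    # confidence from the raw (un-rescaled) responses at the chosen peak:
    # NCC in [-1, 1] clipped to [0, 1], box foreground probability in [0, 1]
    score = float(
        (1.0 - p.alpha) * max(float(corr_raw[iy, ix]), 0.0)
        + p.alpha * float(hist_raw[iy, ix])
    )
    nx = float(np.clip(nx, 0, w - 1))
    ny = float(np.clip(ny, 0, h - 1))
    # appearance and histogram model update at the new position
    patch, _ = crop_patch(img, (nx, ny), state.side)
    template = (1 - p.eta_cf) * state.template + p.eta_cf * (patch * _window(state.side))
    surround, _ = crop_patch(img, (nx, ny), ss)
    ring = np.ones((ss, ss), dtype=bool)
    off = (ss - state.side) // 2
    ring[off : off + state.side, off : off + state.side] = False
    hist_fg = (1 - p.eta_hist) * state.hist_fg + p.eta_hist * _histogram(patch.ravel(), p.n_bins)
    hist_bg = (1 - p.eta_hist) * state.hist_bg + p.eta_hist * _histogram(surround[ring], p.n_bins)
    new_state = TrackerState(template, hist_fg, hist_bg, (nx, ny), state.side, p)
    return (nx, ny), score, new_state


@dataclass
class _LiveTrack:
    track: Track
    state: TrackerState
    low_count: int = 0


def track_video(
    stack,
    detector: Callable[[np.ndarray], Sequence[Detection]],
    params: TrackParams = TrackParams(),
    detect_interval: int = 10,
    gate_radius: float = 20.0,
    max_lost: int = 5,
    min_response: float = 0.2,
) -> list[Track]:
    """Multi-object tracking over a (n_frames, h, w) stack.

    Tracks are seeded from frame-0 detections and stepped every frame.
    Every ``detect_interval`` frames the detector runs again; detections
    are matched to active tracks greedily (descending detection score,
    nearest active center within ``gate_radius``) and unmatched detections
    spawn new tracks. A track whose response stays below ``min_response``
    for ``max_lost`` consecutive frames, or that leaves the frame, is
    terminated.
    """
    stack = np.asarray(as_pixels(stack))
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (n_frames >= 2, h, w)")
    live: list[_LiveTrack] = []
    next_id = 0

    def spawn(det: Detection, frame_idx: int, frame: np.ndarray) -> None:
        nonlocal next_id
        side = params.box_side or det.side
        side += 1 - side % 2
        try:
            state = init_track(frame, det.center, side, params)
        except ValueError:
            return  # detection outside the trackable area
        tr = Track(track_id=next_id, birth_frame=frame_idx)
        tr.append(frame_idx, det.center[0], det.center[1], det.score)
        live.append(_LiveTrack(tr, state))
        next_id += 1

    for det in detector(stack[0]):
        spawn(det, 0, stack[0])

    for f in range(1, stack.shape[0]):
        frame = stack[f]
        for lt in live:
            if lt.track.state != "active":
                continue
            (x, y), score, lt.state = step_track(lt.state, frame)
            lt.track.append(f, x, y, score)
            if lt.state.lost:
                lt.track.state = "terminated"
                lt.track.death_frame = f
                continue
            lt.low_count = lt.low_count + 1 if score < min_response else 0
            if lt.low_count >= max_lost:
                lt.track.state = "terminated"
                lt.track.death_frame = f
        if detect_interval > 0 and f % detect_interval == 0:
            detections = sorted(
                detector(frame), key=lambda d: (-d.score, d.center[0], d.center[1])
            )
            active = [lt for lt in live if lt.track.state == "active"]
            taken: set[int] = set()
            for det in detections:
                best_i, best_d = -1, gate_radius
                for i, lt in enumerate(active):
                    if i in taken:
                        continue
                    cx, cy = lt.state.center
                    d = float(np.hypot(cx - det.center[0], cy - det.center[1]))
                    if d <= best_d:
                        best_i, best_d = i, d
                if best_i >= 0:
                    taken.add(best_i)
                else:
                    spawn(det, f, frame)
    return [lt.track for lt in live]
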