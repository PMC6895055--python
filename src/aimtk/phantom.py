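"""Synthetic-microscopy phantom generator with exact ground truth.

Renders DIC-like transmitted-light (TL) frames and matching fluorescence
(FL) channels for a population of elliptical cells, together with
noise-free truth masks, per-cell morphology classes, true trajectories and
scheduled state-change events. Every downstream stage (label generation,
segmentation, classification, tracking, trajectory analysis) is testable
against these phantoms without any external data.

The TL image is a relief-shaded rendering: the horizontal gradient of a
smoothed cell "height map" added to a mid-gray offset, which mimics the
shear-direction shading of differential interference contrast. FL channels
render one structure each (nucleus, organelles) as flat bright foreground
on a dark background. Camera noise is modelled as Poisson resampling of
the clean image followed by additive Gaussian noise.

All images are float arrays in [0, 1]; identical ``(spec, seed)`` give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import Frame, ROIPatch, Track, crop_patch

__all__ = [
    "CellClass",
    "MotionModel",
    "Event",
    "NoiseModel",
    "PhantomSpec",
    "FrameTruth",
    "VideoTruth",
    "PackingError",
    "render_frame",
    "render_video",
    "simulate_tracks",
    "make_classification_samples",
]

_FL_BACKGROUND = 0.05


class PackingError(ValueError):
    """Raised when cells cannot be placed without overlap."""


@dataclass(frozen=True)
class CellClass:
    """One morphology class.

    eccentricity_range bounds the ellipse eccentricity e in [0, 1);
    texture_contrast modulates the cell body relief; intensity scales both
    the TL relief and the FL foreground level; nucleus_fraction optionally
    overrides the spec-level nucleus radius fraction (used e.g. for a
    "dead" class with a shrunken nucleus).
    """

    name: str
    eccentricity_range: tuple[float, float] = (0.0, 0.3)
    texture_contrast: float = 0.2
    intensity: float = 1.0
    nucleus_fraction: Optional[float] = None


@dataclass(frozen=True)
class MotionModel:
    """Per-frame motion: static, Brownian (D px^2/frame) or persistent walk.

    For Brownian motion each axis steps N(0, sqrt(2D)) so E|dr|^2 = 4D per
    frame, the 2-D diffusion law. Persistent motion moves at ``speed``
    px/frame with a heading random walk whose step std is
    ``(1 - persistence) * pi/2``.
    """

    kind: str = "static"  # static | brownian | persistent
    diffusion: float = 0.0
    speed: float = 0.0
    persistence: float = 0.8

    def __post_init__(self):
        if self.kind not in ("static", "brownian", "persistent"):
            raise ValueError(f"unknown motion kind {self.kind!r}")


@dataclass(frozen=True)
class Event:
    """Scheduled state change of one cell: new class and/or new motion."""

    track_id: int
    frame: int
    new_class: Optional[str] = None
    new_motion: Optional[MotionModel] = None


@dataclass(frozen=True)
class NoiseModel:
    """gaussian_sigma: additive noise std (intensity units);
    poisson_scale: photons per unit intensity (0 disables shot noise)."""

    gaussian_sigma: float = 0.0
    poisson_scale: float = 0.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic field of view / time-lapse."""

    image_size: tuple[int, int] = (256, 256)  # (h, w)
    n_cells: int = 10
    cell_radius_range: tuple[float, float] = (10.0, 16.0)
    nucleus_radius_fraction: float = 0.4
    organelle_mode: str = "none"  # none | puncta | fibers
    class_defs: Sequence[CellClass] = field(default_factory=lambda: (CellClass("cell"),))
    motion: MotionModel = field(default_factory=MotionModel)
    events: Sequence[Event] = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_frames: int = 1
    sample_id: str = "S0"
    seed: int = 0
    tl_gain: float = 2.0
    nucleus_rim_gain: float = 0.8
    nucleus_absorption: float = 0.35
    placement_margin: float = 0.0  # extra center-to-center clearance, px
    initial_classes: Optional[tuple[str, ...]] = None  # pin cell i's class

    def validate(self) -> None:
        h, w = self.image_size
        rmin, rmax = self.cell_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("cell_radius_range must satisfy 0 < min <= max")
        if rmax >= min(h, w) / 4:
            raise ValueError("cell radii must be < min(h, w) / 4")
        if not (0.0 < self.nucleus_radius_fraction < 1.0):
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")
        if self.organelle_mode not in ("none", "puncta", "fibers"):
            raise ValueError(f"unknown organelle_mode {self.organelle_mode!r}")
        if not self.class_defs:
            raise ValueError("at least one cell class is required")
        names = [c.name for c in self.class_defs]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if self.initial_classes is not None:
            bad = set(self.initial_classes) - set(names)
            if bad:
                raise ValueError(f"initial_classes {sorted(bad)} not in class_defs")
        for ev in self.events:
            if not (0 <= ev.frame < self.n_frames):
                raise ValueError(f"event frame {ev.frame} outside [0, {self.n_frames})")
            if not (0 <= ev.track_id < self.n_cells):
                raise ValueError(f"event track_id {ev.track_id} has no cell")
            if ev.new_class is not None and ev.new_class not in names:
                raise ValueError(f"event class {ev.new_class!r} not in class_defs")


@dataclass
class FrameTruth:
    """Noise-free truth for one frame: one integer mask per structure
    (labels are cell instance ids, 0 = background), per-cell class names
    and centers in (x, y)."""

    masks: dict[str, np.ndarray]
    cell_classes: list[str]
    centers: list[tuple[float, float]]


@dataclass
class VideoTruth:
    """Truth for a time-lapse: per-frame masks/classes plus trajectories."""

    frame_truths: list[FrameTruth]
    tracks: list[Track]
    events: list[Event]

    def class_at(self, track_id: int, frame: int) -> str:
        return self.frame_truths[frame].cell_classes[track_id]


# ---------------------------------------------------------------------------
# world construction


@dataclass
class _CellParams:
    center0: np.ndarray  # initial (x, y)
    a: float  # semi-major axis, px
    b: float  # semi-minor axis, px
    phi: float  # orientation, rad
    class_index: int
    puncta: np.ndarray  # (k, 2) offsets in unit-ellipse coords
    fiber_angles: np.ndarray
    texture_phase: float


class _PhantomWorld:
    """Deterministic realization of a PhantomSpec: cell geometry,
    trajectories with events applied, and per-frame class labels."""

    def __init__(self, spec: PhantomSpec):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31), 0]))
        self.cells = self._place_cells(rng)
        self.trajectories, self.class_indices = self._simulate(rng)

    # -- placement ----------------------------------------------------
    def _place_cells(self, rng: np.random.Generator) -> list[_CellParams]:
        spec = self.spec
        h, w = spec.image_size
        rmin, rmax = spec.cell_radius_range
        cells: list[_CellParams] = []
        names = [c.name for c in spec.class_defs]
        for i in range(spec.n_cells):
            r = rng.uniform(rmin, rmax)
            if spec.initial_classes is not None:
                ci = names.index(spec.initial_classes[i % len(spec.initial_classes)])
            else:
                ci = int(rng.integers(len(spec.class_defs)))
            cdef = spec.class_defs[ci]
            e = rng.uniform(*cdef.eccentricity_range)
            # equal-area ellipse: a*b = r^2, b/a = sqrt(1 - e^2)
            ratio = math.sqrt(1.0 - e * e)
            a = r / math.sqrt(ratio)
            b = r * math.sqrt(ratio)
            phi = rng.uniform(0.0, math.pi)
            n_puncta = max(3, int(round(math.pi * r * r / 150.0)))
            puncta = _uniform_disc(rng, n_puncta, 0.7)
            fiber_angles = rng.uniform(0.0, math.pi, size=3)
            phase = rng.uniform(0.0, 2 * math.pi)
            placed = False
            for _ in range(1000):
                cx = rng.uniform(a, w - 1 - a)
                cy = rng.uniform(a, h - 1 - a)
                ok = all(
                    math.hypot(cx - c.center0[0], cy - c.center0[1])
                    > a + c.a + 1.0 + spec.placement_margin
                    for c in cells
                )
                if ok:
                    cells.append(
                        _CellParams(np.array([cx, cy]), a, b, phi, ci, puncta, fiber_angles, phase)
                    )
                    placed = True
                    break
            if not placed:
                raise PackingError(
                    f"could not place cell {i + 1}/{spec.n_cells} without overlap "
                    f"in a {h}x{w} field after 1000 attempts "
                    f"(radius range {spec.cell_radius_range})"
                )
        return cells

    # -- motion -------------------------------------------------------
    def _simulate(self, rng: np.random.Generator):
        """Trajectories (n_cells, n_frames, 2) and per-frame class indices
        (n_cells, n_frames), with events applied at their scheduled frame."""
        spec = self.spec
        h, w = spec.image_size
        n, t = spec.n_cells, spec.n_frames
        name_to_index = {c.name: k for k, c in enumerate(spec.class_defs)}
        motions = [spec.motion] * n
        traj = np.zeros((n, t, 2))
        classes = np.zeros((n, t), dtype=int)
        headings = rng.uniform(0.0, 2 * math.pi, size=n)
        for i, cell in enumerate(self.cells):
            traj[i, 0] = cell.center0
            classes[i, 0] = cell.class_index
        events_by_frame: dict[int, list[Event]] = {}
        for ev in spec.events:
            events_by_frame.setdefault(ev.frame, []).append(ev)
        for ev in events_by_frame.get(0, []):
            if ev.new_class is not None:
                classes[ev.track_id, 0] = name_to_index[ev.new_class]
            if ev.new_motion is not None:
                motions[ev.track_id] = ev.new_motion
        for f in range(1, t):
            for i, cell in enumerate(self.cells):
                m = motions[i]
                if m.kind == "static":
                    step = np.zeros(2)
                elif m.kind == "brownian":
                    step = rng.normal(0.0, math.sqrt(2.0 * m.diffusion), size=2)
                else:  # persistent
                    headings[i] += rng.normal(0.0, (1.0 - m.persistence) * math.pi / 2)
                    step = m.speed * np.array([math.cos(headings[i]), math.sin(headings[i])])
                pos = traj[i, f - 1] + step
                # reflect at borders so the cell stays fully in the field
                pos[0] = _reflect(pos[0], cell.a, w - 1 - cell.a)
                pos[1] = _reflect(pos[1], cell.a, h - 1 - cell.a)
                traj[i, f] = pos
                classes[i, f] = classes[i, f - 1]
            for ev in events_by_frame.get(f, []):
                if ev.new_class is not None:
                    classes[ev.track_id, f] = name_to_index[ev.new_class]
                if ev.new_motion is not None:
                    motions[ev.track_id] = ev.new_motion
        return traj, classes

    # -- rasterization ------------------------------------------------
    def frame_truth(self, frame_index: int) -> FrameTruth:
        spec = self.spec
        h, w = spec.image_size
        cell_mask = np.zeros((h, w), dtype=np.int32)
        nuc_mask = np.zeros((h, w), dtype=np.int32)
        org_mask = np.zeros((h, w), dtype=np.int32)
        classes: list[str] = []
        centers: list[tuple[float, float]] = []
        for i, cell in enumerate(self.cells):
            cx, cy = self.trajectories[i, frame_index]
            cdef = spec.class_defs[self.class_indices[i, frame_index]]
            classes.append(cdef.name)
            centers.append((float(cx), float(cy)))
            sl, q = _ellipse_q(h, w, cx, cy, cell.a, cell.b, cell.phi)
            body = q < 1.0
            cell_mask[sl][body] = i + 1
            nf = cdef.nucleus_fraction
            if nf is None:
                nf = spec.nucleus_radius_fraction
            r_eq = math.sqrt(cell.a * cell.b)
            nsl, nq = _ellipse_q(h, w, cx, cy, nf * r_eq, nf * r_eq, 0.0)
            nuc_mask[nsl][nq < 1.0] = i + 1
            if spec.organelle_mode == "puncta":
                for ox, oy in _world_offsets(cell, cell.puncta):
                    psl, pq = _ellipse_q(h, w, cx + ox, cy + oy, 1.5, 1.5, 0.0)
                    org_mask[psl][pq < 1.0] = i + 1
            elif spec.organelle_mode == "fibers":
                ys, xs = np.nonzero(body)
                if xs.size:
                    gx = xs + sl[1].start - cx
                    gy = ys + sl[0].start - cy
                    hit = np.zeros(xs.shape, dtype=bool)
                    for ang in cell.fiber_angles:
                        d = np.abs(gx * math.sin(ang) - gy * math.cos(ang))
                        hit |= d < 1.0
                    org_mask[ys[hit] + sl[0].start, xs[hit] + sl[1].start] = i + 1
        masks = {"cell": cell_mask, "nucleus": nuc_mask}
        if spec.organelle_mode != "none":
            masks["organelle"] = org_mask
        return FrameTruth(masks, classes, centers)

    def render(self, frame_index: int):
        spec = self.spec
        h, w = spec.image_size
        truth = self.frame_truth(frame_index)
        height = np.zeros((h, w))
        nucleus_height = np.zeros((h, w))
        for i, cell in enumerate(self.cells):
            cx, cy = self.trajectories[i, frame_index]
            cdef = spec.class_defs[self.class_indices[i, frame_index]]
            sl, q = _ellipse_q(h, w, cx, cy, cell.a, cell.b, cell.phi)
            body = q < 1.0
            prof = np.zeros_like(q)
            prof[body] = np.cos(0.5 * math.pi * q[body]) ** 2
            prof[body] *= 1.0 + cdef.texture_contrast * np.cos(
                4 * math.pi * q[body] + cell.texture_phase
            )
            nf = cdef.nucleus_fraction
            if nf is None:
                nf = spec.nucleus_radius_fraction
            r_eq = math.sqrt(cell.a * cell.b)
            # nucleus relief rendered separately (circle, not the body ellipse)
            height[sl] += cdef.intensity * prof
            nsl, nq = _ellipse_q(h, w, cx, cy, nf * r_eq, nf * r_eq, 0.0)
            nprof = np.zeros_like(nq)
            inside = nq < 1.0
            nprof[inside] = np.cos(0.5 * math.pi * nq[inside]) ** 2
            height[nsl] += 0.8 * cdef.intensity * nprof
            # uniform chromatin density: flat absorption disc, sharp edge
            nucleus_height[nsl] += cdef.intensity * inside.astype(float)
        smoothed = ndimage.gaussian_filter(height, sigma=1.0, mode="nearest")
        grad_x = np.gradient(smoothed, axis=1)
        # the denser nucleus is refractile (bright rim) and absorbing
        # (darker interior) on top of the DIC-like relief shading
        smooth_nuc = ndimage.gaussian_filter(nucleus_height, sigma=0.7, mode="nearest")
        rim = ndimage.gaussian_gradient_magnitude(smooth_nuc, 1.0)
        tl = np.clip(
            0.5
            + spec.tl_gain * grad_x
            + spec.nucleus_rim_gain * rim
            - spec.nucleus_absorption * smooth_nuc,
            0.0,
            1.0,
        )

        fl_channels: dict[str, np.ndarray] = {}
        intensity_of = {
            i + 1: spec.class_defs[self.class_indices[i, frame_index]].intensity
            for i in range(spec.n_cells)
        }
        for name in ("nucleus", "organelle"):
            if name not in truth.masks:
                continue
            mask = truth.masks[name]
            fl = np.full((h, w), _FL_BACKGROUND)
            for inst, inten in intensity_of.items():
                fl[mask == inst] = np.clip(_FL_BACKGROUND + 0.9 * inten, 0.0, 1.0)
            fl_channels[name] = fl

        noise_rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed) % (2**31), 1, int(frame_index)])
        )
        tl = _apply_noise(tl, spec.noise, noise_rng)
        fl_frames = [
            Frame(_apply_noise(img, spec.noise, noise_rng), modality=f"fl:{name}")
            for name, img in fl_channels.items()
        ]
        return Frame(tl, modality="tl"), fl_frames, truth

    def tracks(self) -> list[Track]:
        out = []
        for i in range(self.spec.n_cells):
            tr = Track(track_id=i, birth_frame=0)
            for f in range(self.spec.n_frames):
                x, y = self.trajectories[i, f]
                tr.append(f, x, y)
            out.append(tr)
        return out


def _reflect(v: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return (lo + hi) / 2.0
    span = hi - lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return v + lo


def _uniform_disc(rng: np.random.Generator, n: int, rmax: float) -> np.ndarray:
    r = rmax * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * math.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _world_offsets(cell: _CellParams, unit_offsets: np.ndarray):
    """Map unit-ellipse offsets to world (dx, dy) via the cell's axes."""
    c, s = math.cos(cell.phi), math.sin(cell.phi)
    for u, v in unit_offsets:
        ex, ey = u * cell.a, v * cell.b
        yield ex * c - ey * s, ex * s + ey * c


def _ellipse_q(h, w, cx, cy, a, b, phi):
    """Normalized elliptical radius q over a bounding-box slice."""
    reach = max(a, b) + 1.0
    r0 = max(0, int(math.floor(cy - reach)))
    r1 = min(h, int(math.ceil(cy + reach)) + 1)
    c0 = max(0, int(math.floor(cx - reach)))
    c1 = min(w, int(math.ceil(cx + reach)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx, dy = xx - cx, yy - cy
    c, s = math.cos(phi), math.sin(phi)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    return (slice(r0, r1), slice(c0, c1)), np.sqrt(u * u + v * v)


def _apply_noise(img: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = img.astype(float)
    if noise.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma, out.shape)
    if noise.poisson_scale > 0 or noise.gaussian_sigma > 0:
        out = np.clip(out, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# public API


def render_frame(spec: PhantomSpec, frame_index: int = 0):
    """Render one frame: ``(tl, fl_channels, truth)``.

    ``tl`` is a TL :class:`Frame`, ``fl_channels`` a list of FL frames
    (one per structure), ``truth`` the noise-free :class:`FrameTruth`.
    """
    if not (0 <= frame_index < spec.n_frames):
        raise ValueError(f"frame_index {frame_index} outside [0, {spec.n_frames})")
    return _PhantomWorld(spec).render(frame_index)


def render_video(spec: PhantomSpec):
    """Render a full time-lapse: ``(tl_stack, fl_stacks, truth)``.

    ``tl_stack`` is an (n_frames, h, w) float array; ``fl_stacks`` maps
    structure name to a like-shaped array; ``truth`` is a
    :class:`VideoTruth` with per-frame masks and true tracks.
    """
    if spec.n_frames < 2:
        raise ValueError("render_video needs n_frames >= 2")
    world = _PhantomWorld(spec)
    tl_frames = []
    fl_stacks: dict[str, list[np.ndarray]] = {}
    frame_truths = []
    for f in range(spec.n_frames):
        tl, fls, truth = world.render(f)
        tl_frames.append(tl.pixels)
        for fr in fls:
            fl_stacks.setdefault(fr.modality.split(":", 1)[1], []).append(fr.pixels)
        frame_truths.append(truth)
    truth = VideoTruth(frame_truths, world.tracks(), list(spec.events))
    return (
        np.stack(tl_frames),
        {k: np.stack(v) for k, v in fl_stacks.items()},
        truth,
    )


def simulate_tracks(spec: PhantomSpec) -> list[Track]:
    """True trajectories only (no rasterization) — cheap path for
    statistics over many cells/frames."""
    return _PhantomWorld(spec).tracks()


def make_classification_samples(
    specs: Sequence[PhantomSpec],
    roi_side: int = 101,
    rois_per_class: int = 100,
    include_truth: bool = False,
    max_fields: int = 200,
) -> list[ROIPatch]:
    """Build a labelled ROI collection from phantom fields.

    Each spec is one biological sample (its ``sample_id``); fresh fields of
    view are rendered (seeds derived from the spec seed) until every class
    has ``rois_per_class`` ROIs from that sample. ROIs are TL patches
    centered on true cell centers, carrying the true class and sample id.
    With ``include_truth`` the patch also carries its truth cell/nucleus
    mask crops (channels ``truth:cell``, ``truth:nucleus``).
    """
    if roi_side % 2 == 0:
        raise ValueError("roi_side must be odd")
    class_names = sorted({c.name for s in specs for c in s.class_defs})
    if len(class_names) < 2:
        raise ValueError("need at least 2 distinct cell classes across specs")
    samples_per_class: dict[str, set[str]] = {c: set() for c in class_names}
    for s in specs:
        for c in s.class_defs:
            samples_per_class[c.name].add(s.sample_id)
    for cname, sids in samples_per_class.items():
        if len(sids) < 2:
            raise ValueError(f"class {cname!r} present in <2 samples (has {sorted(sids)})")
    patches: list[ROIPatch] = []
    if rois_per_class == 0:
        return patches
    for spec in specs:
        wanted = {c.name: rois_per_class for c in spec.class_defs}
        for field_idx in range(max_fields):
            if all(v == 0 for v in wanted.values()):
                break
            fspec = replace(spec, seed=(int(spec.seed) + 7919 * (field_idx + 1)) % (2**31))
            tl, _, truth = render_frame(fspec, 0)
            for inst, (cname, center) in enumerate(zip(truth.cell_classes, truth.centers), 1):
                if wanted.get(cname, 0) <= 0:
                    continue
                imgs = {}
                patch, padded = crop_patch(tl.pixels, center, roi_side)
                imgs["tl"] = patch
                if include_truth:
                    for mname, mask in truth.masks.items():
                        mcrop, _ = crop_patch((mask == inst).astype(np.uint8), center, roi_side)
                        imgs[f"truth:{mname}"] = mcrop
                patches.append(
                    ROIPatch(
                        images=imgs,
                        center=center,
                        side=roi_side,
                        sample_id=spec.sample_id,
                        label=cname,
                        frame_index=0,
                        padded=padded,
                    )
                )
                wanted[cname] -= 1
        short = {k: v for k, v in wanted.items() if v > 0}
        if short:
            raise ValueError(
                f"sample {spec.sample_id!r}: could not collect enough ROIs for "
                f"classes {short} within {max_fields} fields"
            )
    return patches
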