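"""Shared I/O, run configuration and the end-to-end pipeline.

Stacks are multi-page TIFF (one page per frame) or directories of
PNG/TIFF frames; round-trips are lossless for 8/16-bit integer data.
Label masks are stored as integer-labelled TIFF (never palettized);
tracks and evaluation reports as headered UTF-8 CSV. ``run_pipeline``
chains simulate -> label -> train -> track -> analyze -> evaluate on
phantom data and writes a checksummed manifest beside the resolved
configuration, so a fixed seed reproduces the whole run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import classnet, label_factory, live_analysis, metrics, phantom, tracknet
from .cellnet import PixelSegmenter, SegmenterConfig, build_segmenter, train_segmenter
from .classnet import ProposerConfig, ROIClassifier, propose_cells
from .core import Track
from .label_factory import HKMeansSegmenter
from .phantom import CellClass, Event, MotionModel, NoiseModel, PhantomSpec
from .tracknet import TrackParams

__all__ = [
    "read_stack",
    "write_stack",
    "to_uint16",
    "read_mask",
    "write_mask",
    "tracks_to_frame",
    "tracks_to_csv",
    "tracks_from_csv",
    "save_model",
    "load_model",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("aimtk")

_STACK_SUFFIXES = {".tif", ".tiff", ".png"}


def to_uint16(img: np.ndarray) -> np.ndarray:
    """Scale a float image in [0, 1] to 16-bit for storage."""
    return np.round(np.clip(np.asarray(img, dtype=float), 0.0, 1.0) * 65535).astype(np.uint16)


def write_stack(frames, path) -> Path:
    """Write frames as one multi-page TIFF (one page per frame)."""
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("cannot write an empty stack")
    for i, f in enumerate(frames):
        if f.dtype != frames[0].dtype or f.shape != frames[0].shape:
            raise ValueError(
                f"page {i}: dtype/shape {f.dtype}/{f.shape} differs from page 0 "
                f"({frames[0].dtype}/{frames[0].shape})"
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # grayscale pages, never RGB, regardless of page count
    tifffile.imwrite(path, np.stack(frames), photometric="minisblack")
    return path


def read_stack(path) -> list[np.ndarray]:
    """Read a multi-page TIFF or a directory of per-frame PNG/TIFF files
    (sorted by name). Pages must agree in dtype and shape."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _STACK_SUFFIXES)
        if not files:
            warnings.warn(f"no frames found in {path}", stacklevel=2)
            return []
        frames = []
        for p in files:
            if p.suffix.lower() == ".png":
                import imageio.v3 as iio

                frames.append(np.asarray(iio.imread(p)))
            else:
                frames.append(tifffile.imread(p))
    else:
        data = tifffile.imread(path)
        frames = [data] if data.ndim == 2 else list(data)
    for i, f in enumerate(frames):
        if f.dtype != frames[0].dtype:
            raise ValueError(f"page {i} dtype {f.dtype} differs from page 0 ({frames[0].dtype})")
        if f.shape != frames[0].shape:
            raise ValueError(f"page {i} shape {f.shape} differs from page 0 ({frames[0].shape})")
    return frames


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask).astype(np.int32), photometric="minisblack")
    return path


def read_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for (f, (x, y), s) in zip(t.frames, t.positions, t.scores):
            rows.append((t.track_id, f, x, y, s, t.state))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "response", "state"])


def tracks_to_csv(tracks: list[Track], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tracks_to_frame(tracks).to_csv(path, index=False)
    return path


def tracks_from_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        t = Track(track_id=int(tid), birth_frame=int(g["frame"].iloc[0]),
                  state=str(g["state"].iloc[-1]))
        for _, row in g.iterrows():
            t.append(int(row["frame"]), float(row["x"]), float(row["y"]),
                     float(row["response"]))
        tracks.append(t)
    return tracks


def save_model(model, path) -> Path:
    """Single-file checkpoint with the model's configuration embedded."""
    import joblib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump({"params": model.get_params(), "model": model}, path)
    return path


def load_model(path):
    import joblib

    return joblib.load(Path(path))["model"]


# ---------------------------------------------------------------------------
# run configuration


def _allowed(cls, extra=()) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)} | set(extra)


_SECTION_KEYS = {
    "phantom": _allowed(PhantomSpec),
    "label": {"n_classes", "area_bounds"},
    "segmenter": _allowed(SegmenterConfig)
    | {"epochs", "learning_rate", "pixels_per_class", "n_train_fields", "n_val_fields"},
    "classifier": {"feature_grid", "hidden_units", "epochs", "learning_rate",
                   "roi_side", "rois_per_class"},
    "tracking": _allowed(TrackParams)
    | {"detect_interval", "gate_radius", "max_lost", "min_response",
       "proposer_min_area", "proposer_box_side"},
    "analysis": {"roi_side", "frame_interval_min", "pixel_size_um", "event_rules"},
}
_TOP_KEYS = {"seed", "out_dir", "log_level", *_SECTION_KEYS}


@dataclass
class RunConfig:
    """Nested pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "aim_run"
    log_level: str = "INFO"
    phantom: dict = field(default_factory=dict)
    label: dict = field(default_factory=dict)
    segmenter: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _SECTION_KEYS.items():
            bad = set(raw.get(section, {})) - allowed
            if bad:
                raise ValueError(f"unknown keys in section {section!r}: {sorted(bad)}")
        return cls(**raw)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# pipeline


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _crop_even(img: np.ndarray, center, size: int) -> np.ndarray:
    """Even-sided crop fully inside the image (clipped top-left)."""
    h, w = img.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    r0 = int(np.clip(cy - size // 2, 0, h - size))
    c0 = int(np.clip(cx - size // 2, 0, w - size))
    return img[r0 : r0 + size, c0 : c0 + size]


def _default_classes() -> list[CellClass]:
    return [
        CellClass("round", eccentricity_range=(0.0, 0.25), texture_contrast=0.15,
                  intensity=1.0),
        CellClass("elongated", eccentricity_range=(0.85, 0.95), texture_contrast=0.35,
                  intensity=0.8),
    ]


def make_segmentation_pairs(
    specs, patch_size: int = 64, hk: HKMeansSegmenter | None = None
):
    """(TL patch, HK-means nucleus label mask) training pairs from phantom
    fields — the in-silico staining data-preparation path: labels come
    from the fluorescence channel via intensity clustering, never from the
    ground truth."""
    hk = hk or HKMeansSegmenter(n_classes=2, area_bounds=(20, 10000))
    pairs = []
    for spec in specs:
        tl, fls, truth = phantom.render_frame(spec, 0)
        fl_nuc = next(f for f in fls if f.modality == "fl:nucleus")
        mask = (hk.fit_predict(fl_nuc.pixels) > 0).astype(np.int32)
        for center in truth.centers:
            tl_patch = _crop_even(tl.pixels, center, patch_size)
            mk_patch = _crop_even(mask, center, patch_size)
            pairs.append((tl_patch, mk_patch))
    return pairs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full phantom-to-report chain; returns the manifest.

    Stages: simulate (phantom video + truth), label (HK-means masks from
    the FL nucleus channel), train-seg, train-cls, track, analyze,
    evaluate. Every artifact lands under ``cfg.out_dir`` and is listed in
    the manifest with its SHA-256 checksum.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    seed = int(cfg.seed) % (2**31)
    logger.info("pipeline start: seed=%d out=%s", seed, out)
    manifest: dict[str, dict[str, str]] = {}

    def record(stage: str, path: Path) -> None:
        manifest.setdefault(stage, {})[str(path)] = _sha256(path)

    (out / "config.json").write_text(json.dumps(cfg.resolved(), indent=2, default=str))
    record("config", out / "config.json")

    # --- simulate ---------------------------------------------------------
    ph = dict(cfg.phantom)
    ph.setdefault("image_size", (192, 192))
    ph.setdefault("n_cells", 5)
    ph.setdefault("n_frames", 40)
    ph.setdefault("cell_radius_range", (14.0, 18.0))
    ph.setdefault("nucleus_radius_fraction", 0.5)
    ph.setdefault("placement_margin", 15.0)
    ph.setdefault("class_defs", _default_classes())
    ph.setdefault("motion", MotionModel("brownian", diffusion=0.5))
    ph.setdefault("noise", NoiseModel(gaussian_sigma=0.02, poisson_scale=200.0))
    ph["class_defs"] = [c if isinstance(c, CellClass) else CellClass(**c)
                        for c in ph["class_defs"]]
    if not isinstance(ph.get("motion"), MotionModel):
        ph["motion"] = MotionModel(**ph["motion"])
    if not isinstance(ph.get("noise"), NoiseModel):
        ph["noise"] = NoiseModel(**ph["noise"])
    ph["events"] = [e if isinstance(e, Event) else Event(**e) for e in ph.get("events", [])]
    spec = PhantomSpec(seed=seed, **ph)
    tl_stack, fl_stacks, truth = phantom.render_video(spec)
    record("simulate", write_stack([to_uint16(f) for f in tl_stack], out / "tl_stack.tif"))
    for name, stack in fl_stacks.items():
        record("simulate", write_stack([to_uint16(f) for f in stack], out / f"fl_{name}.tif"))
    record("simulate", tracks_to_csv(truth.tracks, out / "truth_tracks.csv"))

    # --- label ------------------------------------------------------------
    lb = dict(cfg.label)
    hk = HKMeansSegmenter(
        n_classes=int(lb.get("n_classes", 2)),
        area_bounds=tuple(lb.get("area_bounds", (20, 10000))),
    )
    label_mask = (hk.fit_predict(fl_stacks["nucleus"][0]) > 0).astype(np.int32)
    record("label", write_mask(label_mask, out / "hk_mask_f0.tif"))

    # --- train segmenter ---------------------------------------------------
    sg = dict(cfg.segmenter)
    n_train_fields = int(sg.pop("n_train_fields", 6))
    n_val_fields = int(sg.pop("n_val_fields", 2))
    patch_size = int(sg.pop("input_size", 64))
    field_specs = [
        dataclasses.replace(
            spec, n_frames=1, events=(), motion=MotionModel("static"),
            sample_id=f"T{i}", seed=(seed + 101 * (i + 1)) % (2**31),
        )
        for i in range(n_train_fields + n_val_fields)
    ]
    pairs = make_segmentation_pairs(field_specs[:n_train_fields], patch_size, hk)
    val_pairs = make_segmentation_pairs(field_specs[n_train_fields:], patch_size, hk)
    seg_cfg = SegmenterConfig(
        input_size=patch_size,
        n_classes=int(sg.pop("n_classes", 2)),
        depth=int(sg.pop("depth", 2)),
        base_channels=int(sg.pop("base_channels", 64)),
        seed=seed,
    )
    segmenter = build_segmenter(seg_cfg, **{k: sg[k] for k in ("epochs", "learning_rate",
                                                               "pixels_per_class") if k in sg})
    segmenter, seg_report = train_segmenter(segmenter, pairs, val_pairs)
    logger.info("segmenter: best epoch %d, val acc %.4f", seg_report.best_epoch,
                seg_report.val_accuracies[seg_report.best_epoch] if
                seg_report.val_accuracies else float("nan"))
    record("train-seg", save_model(segmenter, out / "segmenter.joblib"))

    # --- train classifier ---------------------------------------------------
    cl = dict(cfg.classifier)
    roi_side = int(cl.pop("roi_side", 41))
    rois_per_class = int(cl.pop("rois_per_class", 60))
    sample_specs = [
        dataclasses.replace(
            spec, n_frames=1, events=(), motion=MotionModel("static"),
            sample_id=f"S{chr(65 + i)}", seed=(seed + 977 * (i + 1)) % (2**31),
        )
        for i in range(3)
    ]
    patches = phantom.make_classification_samples(
        sample_specs, roi_side=roi_side, rois_per_class=rois_per_class
    )
    split = label_factory.assemble_dataset(patches, split_rule=(2, 1))
    classifier, cls_report = classnet.train_classifier(split, seed=seed, **cl)
    record("train-cls", save_model(classifier, out / "classifier.joblib"))

    # --- track --------------------------------------------------------------
    tk = dict(cfg.tracking)
    box_side = int(tk.pop("proposer_box_side", 41))
    min_area = float(tk.pop("proposer_min_area", 30.0))
    prop_cfg = ProposerConfig(method="blob", box_side=box_side, min_area=min_area)
    track_kwargs = {k: tk.pop(k) for k in ("detect_interval", "gate_radius", "max_lost",
                                           "min_response") if k in tk}
    params = TrackParams(**tk)
    tracks = tracknet.track_video(
        tl_stack, lambda fr: propose_cells(fr, prop_cfg), params, **track_kwargs
    )
    record("track", tracks_to_csv(tracks, out / "tracks.csv"))

    # --- analyze -------------------------------------------------------------
    an = dict(cfg.analysis)
    reports = [
        live_analysis.analyze_trajectory(
            t, tl_stack, segmenter=segmenter, classifiers={"morphology": classifier},
            roi_side=int(an.get("roi_side", roi_side)),
            frame_interval_min=float(an.get("frame_interval_min", 5.0)),
            pixel_size_um=float(an.get("pixel_size_um", 1.0)),
        )
        for t in tracks
        if len(t) >= 2
    ]
    if reports:
        tidy = pd.concat([r.to_frame() for r in reports], ignore_index=True)
        tidy.to_csv(out / "trajectory_report.csv", index=False)
        record("analyze", out / "trajectory_report.csv")

    # --- evaluate -------------------------------------------------------------
    pred, _ = segmenter.predict(tl_stack[0], tile=True), None
    truth_mask = (truth.frame_truths[0].masks["nucleus"] > 0).astype(np.int32)
    pred_b = (pred > 0).astype(np.int32)
    scores = {
        "recall": metrics.pixel_recall(pred_b, truth_mask).get(1, 1.0),
        "iou": metrics.iou_score(pred_b, truth_mask).get(1, 1.0),
        "bf": metrics.bf_score(pred_b, truth_mask),
        "n_tracks": len(tracks),
    }
    (out / "evaluation.json").write_text(json.dumps(scores, indent=2))
    record("evaluate", out / "evaluation.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline done: %s", scores)
    return manifest
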