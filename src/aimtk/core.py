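"""Shared containers and conventions.

Coordinate convention used everywhere in this package: positions are
``(x, y) = (column, row)``, 0-based, with pixel centers at integer
coordinates. Arrays are indexed ``array[row, column]`` as usual for numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Frame",
    "ROIPatch",
    "Track",
    "as_pixels",
    "crop_patch",
    "round_half_away",
]


@dataclass
class Frame:
    """One 2-D grayscale image with acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of shape (h, w)
        Image data.
    modality : str
        Channel tag, e.g. ``"tl"`` for transmitted light or
        ``"fl:nucleus"`` for a fluorescence channel.
    pixel_size_um : float
        Physical side of one pixel in micrometres.
    """

    pixels: np.ndarray
    modality: str = "tl"
    pixel_size_um: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ROIPatch:
    """Odd-sided square crop centered on a point, with provenance.

    ``images`` maps a channel name (e.g. ``"tl"``) to the cropped pixels.
    """

    images: dict[str, np.ndarray]
    center: tuple[float, float]  # (x, y) in source-frame coordinates
    side: int
    sample_id: str = ""
    label: Optional[str] = None
    frame_index: int = 0
    padded: bool = False

    @property
    def image(self) -> np.ndarray:
        """The transmitted-light channel if present, else the first channel."""
        if "tl" in self.images:
            return self.images["tl"]
        return next(iter(self.images.values()))


@dataclass
class Track:
    """Identified sequence of positions of one object over time."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)  # (x, y)
    scores: list[float] = field(default_factory=list)
    state: str = "active"  # active | lost | terminated
    birth_frame: int = 0
    death_frame: Optional[int] = None

    def append(self, frame: int, x: float, y: float, score: float = 1.0) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("track frames must be strictly increasing")
        self.frames.append(frame)
        self.positions.append((float(x), float(y)))
        self.scores.append(float(score))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def xy(self) -> np.ndarray:
        """Positions as an (n, 2) array of (x, y)."""
        return np.asarray(self.positions, dtype=float).reshape(-1, 2)


def as_pixels(frame) -> np.ndarray:
    """Return the pixel array of a Frame or pass an ndarray through."""
    if isinstance(frame, Frame):
        return frame.pixels
    return np.asarray(frame)


def round_half_away(v) -> np.ndarray:
    """Round half away from zero (documented centroid tie-break)."""
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def crop_patch(image: np.ndarray, center_xy: tuple[float, float], side: int):
    """Crop an odd-sided square patch centered at the nearest pixel.

    Out-of-bounds regions are reflect-padded. Returns ``(patch, padded)``
    where ``padded`` flags whether any padding was needed.
    """
    if side % 2 == 0:
        raise ValueError(f"patch side must be odd, got {side}")
    image = np.asarray(image)
    h, w = image.shape
    cx, cy = (int(round_half_away(center_xy[0])), int(round_half_away(center_xy[1])))
    half = side // 2
    r0, r1 = cy - half, cy + half + 1
    c0, c1 = cx - half, cx + half + 1
    padded = r0 < 0 or c0 < 0 or r1 > h or c1 > w
    if not padded:
        return image[r0:r1, c0:c1].copy(), False
    pad_top = max(0, -r0)
    pad_bot = max(0, r1 - h)
    pad_left = max(0, -c0)
    pad_right = max(0, c1 - w)
    big = np.pad(image, ((pad_top, pad_bot), (pad_left, pad_right)), mode="reflect")
    r0 += pad_top
    c0 += pad_left
    return big[r0 : r0 + side, c0 : c0 + side].copy(), True
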