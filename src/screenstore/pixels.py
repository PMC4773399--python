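"""Per-plane intensity statistics and windowed thumbnail rendering.

These are the "simple" calculations that nonetheless dominate interactive
use of an image store: min/max/mean/median of a plane, and re-rendering a
small RGB preview whenever a user changes the per-channel display window.

Rendering model: each active channel is linearly windowed,
``w = clamp((v - window_min) / (window_max - window_min), 0, 1)``,
scaled to [0, 255], tinted by the channel's RGB colour, and the tinted
channels are summed with saturation at 255.  Downsampling is block-mean
over the largest integer factor, then nearest-neighbour to the exact
target size; final values round half-up.  Every step is deterministic, so
identical settings give byte-identical thumbnails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .errors import PlaneError, RenderSettingsError


class PlaneStats(NamedTuple):
    min: float
    max: float
    mean: float
    median: float


def plane_stats(plane) -> PlaneStats:
    """Exact (min, max, mean, median) of a non-empty numeric plane.

    The median of an even-sized sample is the midpoint of the two central
    order statistics.
    """
    arr = np.asarray(plane, dtype=float)
    if arr.size == 0:
        raise PlaneError("plane is empty")
    return PlaneStats(float(arr.min()), float(arr.max()),
                      float(arr.mean()), float(np.median(arr)))


@dataclass(frozen=True)
class ChannelSettings:
    """Display window and tint colour for one channel."""

    window_min: float
    window_max: float
    color: tuple[int, int, int] = (255, 255, 255)
    active: bool = True


@dataclass(frozen=True)
class RenderingSettings:
    channels: tuple[ChannelSettings, ...] = field(default_factory=tuple)

    def __init__(self, channels: Sequence[ChannelSettings]):
        object.__setattr__(self, "channels", tuple(channels))
        for i, ch in enumerate(self.channels):
            if ch.active and not ch.window_min < ch.window_max:
                raise RenderSettingsError(
                    f"channel {i}: window [{ch.window_min}, {ch.window_max}] "
                    "is inverted or empty")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _downsample(rgb: np.ndarray, max_edge: int) -> np.ndarray:
    """Block-mean by the largest integer factor, then nearest-neighbour."""
    h, w = rgb.shape[:2]
    long_edge = max(h, w)
    target_long = min(max_edge, long_edge)
    if target_long == long_edge:
        return rgb
    th = max(1, int(_round_half_up(np.array(h * target_long / long_edge))))
    tw = max(1, int(_round_half_up(np.array(w * target_long / long_edge))))
    if h == long_edge:
        th = target_long
    else:
        tw = target_long
    f = max(1, long_edge // target_long)
    if f > 1:
        ch, cw = (h // f) * f, (w // f) * f
        blocks = rgb[:ch, :cw].reshape(ch // f, f, cw // f, f, 3)
        rgb = blocks.mean(axis=(1, 3))
    # nearest-neighbour to the exact target
    hh, ww = rgb.shape[:2]
    yi = np.minimum((np.arange(th) + 0.5) * hh / th, hh - 1).astype(int)
    xi = np.minimum((np.arange(tw) + 0.5) * ww / tw, ww - 1).astype(int)
    return rgb[np.ix_(yi, xi)]


def render_thumbnail(planes: Sequence[np.ndarray], settings: RenderingSettings,
                     max_edge: int = 96) -> np.ndarray:
    """Render per-channel planes into one RGB uint8 thumbnail.

    *planes* and ``settings.channels`` must correspond one-to-one; the
    longer output edge equals ``min(max_edge, longer input edge)`` with
    aspect preserved.
    """
    if max_edge < 1:
        raise RenderSettingsError(f"max_edge must be >= 1, got {max_edge}")
    if len(planes) != len(settings.channels):
        raise RenderSettingsError(
            f"{len(planes)} plane(s) but settings cover {len(settings.channels)} "
            "channel(s)")
    if not planes:
        raise PlaneError("no planes to render")
    shape = np.asarray(planes[0]).shape
    acc = np.zeros(shape + (3,), dtype=float)
    for plane, ch in zip(planes, settings.channels):
        if not ch.active:
            continue
        arr = np.asarray(plane, dtype=float)
        if arr.shape != shape:
            raise PlaneError(f"plane shapes differ: {arr.shape} vs {shape}")
        w = np.clip((arr - ch.window_min) / (ch.window_max - ch.window_min), 0.0, 1.0)
        scaled = w * 255.0
        for band in range(3):
            acc[..., band] += scaled * (ch.color[band] / 255.0)
    acc = np.minimum(acc, 255.0)
    acc = _downsample(acc, max_edge)
    return np.clip(_round_half_up(acc), 0, 255).astype(np.uint8)


def read_plane_tiff(path: str | Path) -> np.ndarray:
    """Read a single-plane grayscale TIFF (baseline, uncompressed)."""
    import tifffile

    arr = tifffile.imread(str(path))
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise PlaneError(f"{path} is not a single grayscale plane (shape {arr.shape})")
    return arr


def write_png(rgb: np.ndarray, path: str | Path) -> None:
    """Write an RGB uint8 array as PNG."""
    from PIL import Image as PILImage

    PILImage.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(str(path))
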