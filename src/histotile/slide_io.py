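"""Pyramidal slide reading.

Whole-slide images are stored as multi-resolution pyramids: level 0 holds
the native-resolution raster and each further level a pre-computed
downsampled copy.  This module opens tiled pyramidal TIFF / Aperio SVS
files (and, as a degraded fallback, plain single-resolution RGB images)
and serves rectangular regions at arbitrary downsample factors.

Conventions
-----------
* Coordinates are 0-based, half-open, ``(x = column, y = row)``.
* Region origins ``(x, y)`` are always expressed at native (level-0)
  resolution; region sizes ``(w, h)`` at the requested output resolution.
* A downsample factor ``d >= 1`` means one output pixel spans ``d x d``
  native pixels.  Factors that do not match a stored level are served by
  reading the nearest finer stored level and box (area-average)
  resampling.

Images are represented as numpy arrays throughout: RGB rasters as
``uint8`` arrays of shape ``(h, w, 3)`` (row-major, so ``arr[y, x]``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import BoundsError, FormatError, InputError, ParameterError

__all__ = ["SlideHandle", "open_slide", "read_region", "read_full", "best_level_for_downsample"]


@dataclass
class SlideHandle:
    """An open pyramidal slide with all levels resident in memory.

    ``level_dims`` are ``(width, height)`` pairs, level 0 first (largest);
    ``level_downsamples`` start at 1 and ascend.  Synthetic and test-scale
    slides comfortably fit in memory, which keeps region reads trivial and
    deterministic; the public contract (per-region reads at any factor)
    would be unchanged by a lazier backend.
    """

    path: Path
    level_count: int
    level_dims: list[tuple[int, int]]
    level_downsamples: list[float]
    _levels: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def dimensions(self) -> tuple[int, int]:
        """Native ``(width, height)``."""
        return self.level_dims[0]


def _composite_over_white(arr: np.ndarray) -> np.ndarray:
    """Drop an alpha channel by compositing over a white background."""
    if arr.ndim == 3 and arr.shape[2] == 4:
        rgb = arr[..., :3].astype(np.float64)
        alpha = arr[..., 3:4].astype(np.float64) / 255.0
        out = rgb * alpha + 255.0 * (1.0 - alpha)
        return np.round(out).clip(0, 255).astype(np.uint8)
    return arr


def _as_rgb(arr: np.ndarray, path: Path) -> np.ndarray:
    """Coerce a decoded page to (h, w, 3) uint8."""
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = _composite_over_white(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected an RGB(A) or grayscale raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit samples, got {arr.dtype}")
    return np.ascontiguousarray(arr)


def open_slide(path: str | Path) -> SlideHandle:
    """Open a pyramidal TIFF/SVS or plain RGB image as a slide.

    Plain images (PNG, single-page TIFF) become single-level pyramids with
    ``level_downsamples == [1.0]``.

    Raises
    ------
    InputError
        If *path* does not exist.
    FormatError
        If the file cannot be decoded as an image.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"slide file not found: {path}")

    levels: list[np.ndarray] | None = None
    if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
        try:
            with tifffile.TiffFile(path) as tf:
                series = tf.series[0]
                levels = [_as_rgb(np.asarray(lv.asarray()), path) for lv in series.levels]
        except (tifffile.TiffFileError, ValueError, IndexError) as exc:
            raise FormatError(f"cannot read TIFF slide {path}: {exc}") from exc
    else:
        try:
            with Image.open(path) as im:
                im.load()
                if im.mode not in ("RGB", "RGBA", "L"):
                    im = im.convert("RGBA")
                levels = [_as_rgb(np.asarray(im), path)]
        except (OSError, ValueError) as exc:
            raise FormatError(f"cannot read image {path}: {exc}") from exc

    dims = [(lv.shape[1], lv.shape[0]) for lv in levels]
    w0, h0 = dims[0]
    downs = [w0 / w for (w, _h) in dims]
    handle = SlideHandle(
        path=path,
        level_count=len(levels),
        level_dims=dims,
        level_downsamples=downs,
        _levels=levels,
    )
    _check_pyramid(handle)
    return handle


def _check_pyramid(handle: SlideHandle) -> None:
    w0, h0 = handle.level_dims[0]
    if abs(handle.level_downsamples[0] - 1.0) > 1e-9:
        raise FormatError(f"{handle.path}: level 0 downsample is not 1")
    prev = 0.0
    for i, ((w, h), d) in enumerate(zip(handle.level_dims, handle.level_downsamples)):
        if d < prev:
            raise FormatError(f"{handle.path}: level downsamples not ascending at level {i}")
        prev = d
        if abs(w0 / d - w) > 1 or abs(h0 / d - h) > 1:
            raise FormatError(f"{handle.path}: level {i} dimensions inconsistent with its downsample")


def best_level_for_downsample(handle: SlideHandle, factor: float) -> tuple[int, float]:
    """Largest stored level with downsample <= *factor*, plus residual scale.

    The residual scale ``factor / level_downsamples[level]`` is >= 1 and
    is the extra box-resampling the caller must apply.
    """
    if factor < 1:
        raise ParameterError(f"downsample factor must be >= 1, got {factor}")
    level = 0
    for i, d in enumerate(handle.level_downsamples):
        if d <= factor + 1e-9:
            level = i
    return level, factor / handle.level_downsamples[level]


def _box_resize(arr: np.ndarray, w: int, h: int) -> np.ndarray:
    """Area-average (box) resample an RGB array to (h, w)."""
    if arr.shape[0] == h and arr.shape[1] == w:
        return arr
    im = Image.fromarray(arr, mode="RGB")
    return np.asarray(im.resize((w, h), resample=Image.Resampling.BOX))


def read_region(
    handle: SlideHandle, downsample: float, x: int, y: int, w: int, h: int
) -> np.ndarray:
    """Read a region as an (h, w, 3) uint8 array.

    ``(x, y)`` is the native-resolution top-left; ``(w, h)`` the output
    size, so the native footprint is ``w * downsample`` by
    ``h * downsample`` pixels and must lie within level-0 bounds.
    """
    if downsample < 1:
        raise ParameterError(f"downsample factor must be >= 1, got {downsample}")
    if w <= 0 or h <= 0:
        raise ParameterError(f"region size must be positive, got ({w}, {h})")
    w0, h0 = handle.dimensions
    nat_w = w * downsample
    nat_h = h * downsample
    if x < 0 or y < 0 or x + nat_w > w0 + 1e-6 or y + nat_h > h0 + 1e-6:
        raise BoundsError(
            f"region x={x}, y={y}, w={w}, h={h} at downsample {downsample} "
            f"(native footprint {nat_w:g} x {nat_h:g}) exceeds slide bounds {w0} x {h0}"
        )

    level, residual = best_level_for_downsample(handle, downsample)
    src = handle._levels[level]
    ds = handle.level_downsamples[level]
    lx = int(round(x / ds))
    ly = int(round(y / ds))
    lw = int(round(w * residual))
    lh = int(round(h * residual))
    lw = min(lw, src.shape[1] - lx)
    lh = min(lh, src.shape[0] - ly)
    crop = src[ly : ly + lh, lx : lx + lw]
    return _box_resize(crop, w, h)


def read_full(handle: SlideHandle, downsample: float) -> np.ndarray:
    """Read the whole slide at *downsample* (dimensions floor(native/d))."""
    w0, h0 = handle.dimensions
    w = max(1, math.floor(w0 / downsample))
    h = max(1, math.floor(h0 / downsample))
    return read_region(handle, downsample, 0, 0, w, h)
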