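"""Synthetic pyramidal slides with known ground truth.

Real whole-slide images are multi-gigabyte and access-controlled; every
stage of this package is instead exercised against generated slides that
mimic their salient structure: irregular stained-tissue blobs on a
near-white scanner background, written as tiled pyramidal TIFF together
with a pixel-exact foreground mask.

A blob is the union of a few randomly perturbed ellipses sharing a
center, filled with an eosin-like pink whose per-blob shade varies, over
a bright background; i.i.d. Gaussian pixel noise is added everywhere.
With ``perturbation = 0`` every lobe collapses to an exact circle of the
drawn radius, which gives the analytic-area oracle used in tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
import tifffile

from .errors import ParameterError

__all__ = [
    "SyntheticSlideSpec",
    "generate_synthetic_slide",
    "load_ground_truth",
    "blob_tile_ground_truth",
]

# Tissue-section-like defaults: blobs span ~1/8 to 1/4 of the slide so a
# 256 px tile grid sees both interior and boundary tiles; stain contrast
# against background (~242 vs ~148 gray) is strong, as for H&E on glass.
@dataclass
class SyntheticSlideSpec:
    width: int = 4096
    height: int = 4096
    n_blobs: int = 5
    blob_radius_range: tuple[float, float] = (250.0, 500.0)
    stain_color_mean: tuple[float, float, float] = (200.0, 120.0, 160.0)
    stain_color_sd: float = 12.0
    background_level: float = 242.0
    noise_sd: float = 6.0
    levels: tuple[int, ...] = (1, 4, 16)
    seed: int = 0
    lobes_per_blob: int = 3
    perturbation: float = 0.35

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("slide dimensions must be positive")
        lo, hi = self.blob_radius_range
        if lo <= 0 or hi < lo:
            raise ParameterError(f"invalid blob radius range {self.blob_radius_range}")
        if not 200 <= self.background_level <= 255:
            raise ParameterError("background_level must lie in [200, 255]")
        if len(self.levels) == 0 or self.levels[0] != 1:
            raise ParameterError("pyramid levels must start with 1")
        if any(f < 1 for f in self.levels):
            raise ParameterError("pyramid levels must be >= 1")
        if self.n_blobs < 0 or self.lobes_per_blob < 1:
            raise ParameterError("blob counts must be non-negative")
        if self.perturbation < 0:
            raise ParameterError("perturbation must be >= 0")


def _fill_ellipse(mask: np.ndarray, cx: float, cy: float, a: float, b: float, theta: float) -> None:
    """Set True inside the rotated ellipse; edits *mask* in place."""
    h, w = mask.shape
    r = max(a, b)
    x0 = max(0, int(np.floor(cx - r)))
    x1 = min(w, int(np.ceil(cx + r)) + 1)
    y0 = max(0, int(np.floor(cy - r)))
    y1 = min(h, int(np.ceil(cy + r)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - cx
    dy = ys - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    mask[y0:y1, x0:x1] |= (u * u + v * v) <= 1.0


def _box_downsample(arr: np.ndarray, f: int) -> np.ndarray:
    """Integer-factor area-average downsampling (trailing remainder trimmed)."""
    h = (arr.shape[0] // f) * f
    w = (arr.shape[1] // f) * f
    a = arr[:h, :w].astype(np.float64)
    a = a.reshape(h // f, f, w // f, f, -1).mean(axis=(1, 3))
    return np.round(a).clip(0, 255).astype(np.uint8)


def generate_synthetic_slide(
    spec: SyntheticSlideSpec, out_dir: str | Path, stem: str = "synthetic_slide"
) -> tuple[Path, np.ndarray]:
    """Write a synthetic pyramidal TIFF slide; return (path, ground-truth mask).

    The ground-truth mask is a native-resolution boolean array, True
    exactly on blob pixels (before noise).  Alongside the TIFF the
    function writes ``<stem>_mask.png`` and a JSON sidecar echoing the
    spec.  Identical spec + seed produce byte-identical files.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height

    truth = np.zeros((h, w), dtype=bool)
    r_lo, r_hi = spec.blob_radius_range
    # Keep blobs clear of the slide border so border-exclusion background
    # classification stays well-posed on fixtures: lobe offsets are
    # clamped to 2 sd below, so the worst-case lobe extent is
    # (1 + perturbation) * r for the axis plus 2 * perturbation * r offset.
    margin = min(r_hi * (1.0 + 3.0 * spec.perturbation) + 4, (min(w, h) - 1) / 2)
    blob_colors = []
    for _ in range(spec.n_blobs):
        cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2
        cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
        radius = rng.uniform(r_lo, r_hi)
        color = np.array(spec.stain_color_mean) + rng.normal(0.0, spec.stain_color_sd, size=3)
        blob_mask = np.zeros_like(truth)
        for lobe in range(spec.lobes_per_blob):
            if spec.perturbation == 0.0:
                ox = oy = 0.0
                a = b = radius
                theta = 0.0
            else:
                sd = spec.perturbation * radius
                ox, oy = np.clip(rng.normal(0.0, sd, size=2), -2 * sd, 2 * sd)
                a = radius * (1.0 + rng.uniform(-spec.perturbation, spec.perturbation))
                b = radius * (1.0 + rng.uniform(-spec.perturbation, spec.perturbation))
                theta = rng.uniform(0.0, np.pi)
            _fill_ellipse(blob_mask, cx + ox, cy + oy, a, b, theta)
        truth |= blob_mask
        blob_colors.append((blob_mask, color))

    img = np.full((h, w, 3), spec.background_level, dtype=np.float64)
    for blob_mask, color in blob_colors:
        img[blob_mask] = color
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    native = np.round(img).clip(0, 255).astype(np.uint8)

    pyramid = [native]
    for f in spec.levels[1:]:
        pyramid.append(_box_downsample(native, int(f)))

    tiff_path = out_dir / f"{stem}.tiff"
    with tifffile.TiffWriter(tiff_path) as tw:
        tw.write(
            pyramid[0], tile=(256, 256), photometric="rgb", subifds=len(pyramid) - 1
        )
        for lv in pyramid[1:]:
            tw.write(lv, tile=(256, 256), photometric="rgb", subfiletype=1)

    Image.fromarray(truth.astype(np.uint8) * 255, mode="L").save(out_dir / f"{stem}_mask.png")
    sidecar = asdict(spec)
    sidecar["levels"] = list(spec.levels)
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return tiff_path, truth


def load_ground_truth(slide_path: str | Path) -> np.ndarray:
    """Load the boolean ground-truth mask written next to a fixture slide."""
    slide_path = Path(slide_path)
    mask_path = slide_path.with_name(slide_path.stem + "_mask.png")
    return np.asarray(Image.open(mask_path)) > 127


def blob_tile_ground_truth(
    mask: np.ndarray, tile_size: int, threshold: float
) -> set[tuple[int, int]]:
    """Grid cells whose true-pixel fraction >= threshold, by direct counting.

    ``tile_size`` is in pixels of *mask*; partial edge cells are padded
    with background, so the denominator is always the full tile area.
    Serves as the selection oracle for the tiler.
    """
    if tile_size <= 0:
        raise ParameterError("tile_size must be positive")
    h, w = mask.shape
    n_rows = -(-h // tile_size)
    n_cols = -(-w // tile_size)
    padded = np.zeros((n_rows * tile_size, n_cols * tile_size), dtype=bool)
    padded[:h, :w] = mask
    counts = padded.reshape(n_rows, tile_size, n_cols, tile_size).sum(axis=(1, 3))
    frac = counts / float(tile_size * tile_size)
    rows, cols = np.nonzero(frac >= threshold)
    return set(zip(rows.tolist(), cols.tolist()))
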