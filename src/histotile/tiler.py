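"""Tile grid, foreground scoring, selection, and extraction.

The grid is defined purely by the native slide size, the tile size (in
output-resolution pixels) and the output downsample, so its geometry is
identical for any mask downsample — masks only decide which tiles are
kept.  A tile's mask-level footprint side is
``tile_size * output_downsample / mask_downsample``; its foreground
fraction is the number of foreground mask pixels in the footprint over
the *full* footprint area (padding beyond the slide counts as
background).  Partial edge tiles are kept and padded white on
extraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import slide_io
from .errors import ConfigError, ParameterError, StructuralError
from .mask_methods import BinaryMask

__all__ = [
    "GridSpec",
    "TileRecord",
    "compute_tile_grid",
    "score_tiles",
    "select_tiles",
    "extract_tiles",
    "sample_random_tiles",
]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["slide", "row", "col", "x", "y", "width", "height", "fg_fraction", "selected"]


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry and selection policy for one run."""

    native_w: int
    native_h: int
    tile_size: int = 256
    output_downsample: float = 1.0
    mask_downsample: float = 16.0
    content_threshold: float = 0.05
    keep_all: bool = False

    @property
    def native_span(self) -> float:
        """Native pixels covered by one tile side."""
        return self.tile_size * self.output_downsample

    @property
    def mask_tile_side(self) -> float:
        """Tile side length in mask pixels."""
        return self.native_span / self.mask_downsample

    @property
    def n_cols(self) -> int:
        return math.ceil(self.native_w / self.native_span)

    @property
    def n_rows(self) -> int:
        return math.ceil(self.native_h / self.native_span)

    def validate(self) -> None:
        if self.tile_size < 1:
            raise ParameterError(f"tile_size must be >= 1, got {self.tile_size}")
        if self.output_downsample < 1 or self.mask_downsample < 1:
            raise ParameterError("downsample factors must be >= 1")
        if not 0 <= self.content_threshold <= 1:
            raise ParameterError(
                f"content_threshold must lie in [0, 1], got {self.content_threshold}"
            )
        if self.mask_tile_side < 1:
            raise ConfigError(
                f"tile footprint at mask resolution is {self.mask_tile_side:.3f} px "
                f"(< 1): reduce mask_downsample below "
                f"{self.native_span:g} or enlarge the tiles"
            )


@dataclass
class TileRecord:
    """One grid cell: position, native coordinates, score, selection flag."""

    row: int
    col: int
    x: int
    y: int
    width: int
    height: int
    fg_fraction: float = 0.0
    selected: bool = False


def compute_tile_grid(native_w: int, native_h: int, grid: GridSpec) -> list[TileRecord]:
    """Row-major unscored records covering the slide (edge tiles included)."""
    grid.validate()
    if (native_w, native_h) != (grid.native_w, grid.native_h):
        raise StructuralError("native dimensions disagree with the grid spec")
    span = grid.native_span
    records = []
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            records.append(
                TileRecord(
                    row=row,
                    col=col,
                    x=int(round(col * span)),
                    y=int(round(row * span)),
                    width=grid.tile_size,
                    height=grid.tile_size,
                )
            )
    return records


def score_tiles(records: list[TileRecord], mask: BinaryMask, grid: GridSpec) -> list[TileRecord]:
    """Fill fg_fraction from the mask; full-tile-area denominator."""
    if mask.downsample != grid.mask_downsample:
        raise StructuralError(
            f"mask downsample {mask.downsample} != grid mask_downsample {grid.mask_downsample}"
        )
    if (
        abs(mask.width * mask.downsample - grid.native_w) > 2 * mask.downsample
        or abs(mask.height * mask.downsample - grid.native_h) > 2 * mask.downsample
    ):
        raise StructuralError(
            f"mask dimensions {mask.width} x {mask.height} at downsample {mask.downsample} "
            f"do not cover the slide {grid.native_w} x {grid.native_h}"
        )
    s = grid.mask_tile_side
    fg = mask.fg
    # Row/column prefix sums make each footprint count O(1).
    integral = np.zeros((fg.shape[0] + 1, fg.shape[1] + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(fg, axis=0), axis=1)

    out = []
    for rec in records:
        x0 = int(round(rec.col * s))
        x1 = int(round((rec.col + 1) * s))
        y0 = int(round(rec.row * s))
        y1 = int(round((rec.row + 1) * s))
        area = (x1 - x0) * (y1 - y0)
        cx0, cx1 = min(x0, fg.shape[1]), min(x1, fg.shape[1])
        cy0, cy1 = min(y0, fg.shape[0]), min(y1, fg.shape[0])
        count = int(
            integral[cy1, cx1] - integral[cy0, cx1] - integral[cy1, cx0] + integral[cy0, cx0]
        )
        out.append(replace(rec, fg_fraction=count / area if area else 0.0))
    return out


def select_tiles(
    records: list[TileRecord], content_threshold: float, keep_all: bool = False
) -> list[TileRecord]:
    """selected iff fg_fraction >= threshold; keep_all overrides."""
    if not 0 <= content_threshold <= 1:
        raise ParameterError(f"content_threshold must lie in [0, 1], got {content_threshold}")
    return [
        replace(rec, selected=keep_all or rec.fg_fraction >= content_threshold)
        for rec in records
    ]


def _read_padded_tile(
    slide: slide_io.SlideHandle, x: int, y: int, tile_size: int, downsample: float
) -> np.ndarray:
    """Read a tile at (x, y), white-padding any part beyond the slide."""
    w0, h0 = slide.dimensions
    avail_w = int((w0 - x) // downsample)
    avail_h = int((h0 - y) // downsample)
    rw = min(tile_size, avail_w)
    rh = min(tile_size, avail_h)
    canvas = np.full((tile_size, tile_size, 3), 255, dtype=np.uint8)
    if rw > 0 and rh > 0:
        canvas[:rh, :rw] = slide_io.read_region(slide, downsample, x, y, rw, rh)
    return canvas


def _manifest_frame(stem: str, records: list[TileRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "slide": stem,
            "row": [r.row for r in records],
            "col": [r.col for r in records],
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "width": [r.width for r in records],
            "height": [r.height for r in records],
            "fg_fraction": [f"{r.fg_fraction:.6f}" for r in records],
            "selected": [int(r.selected) for r in records],
        },
        columns=MANIFEST_COLUMNS,
    )


def extract_tiles(
    slide: slide_io.SlideHandle,
    records: list[TileRecord],
    grid: GridSpec,
    out_dir: str | Path,
) -> tuple[list[Path], Path]:
    """Write one PNG per selected tile plus a TSV manifest of every tile.

    Tiles are named ``<slide_stem>_<row>_<col>.png``, exactly
    ``tile_size`` square, white-padded beyond the slide edge.  The
    manifest covers the full grid (selected and rejected rows alike).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    stem = slide.path.stem

    written: list[Path] = []
    for rec in records:
        if not rec.selected:
            continue
        tile = _read_padded_tile(slide, rec.x, rec.y, grid.tile_size, grid.output_downsample)
        path = out_dir / f"{stem}_{rec.row}_{rec.col}.png"
        Image.fromarray(tile, mode="RGB").save(path)
        written.append(path)
    if not written:
        logger.warning("no tiles met the content threshold; only the manifest was written")

    manifest_path = out_dir / f"{stem}_manifest.tsv"
    _manifest_frame(stem, records).to_csv(manifest_path, sep="\t", index=False)
    return written, manifest_path


def random_tile_origins(
    native_w: int, native_h: int, tile_size: int, output_downsample: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform native top-left coordinates for n random tiles."""
    span = int(math.ceil(tile_size * output_downsample))
    if span > native_w or span > native_h:
        raise ParameterError(
            f"tile footprint {span} px exceeds slide dimensions {native_w} x {native_h}"
        )
    rng = np.random.default_rng(seed)
    xs = rng.integers(0, native_w - span + 1, size=n)
    ys = rng.integers(0, native_h - span + 1, size=n)
    return xs, ys


def sample_random_tiles(
    slide: slide_io.SlideHandle,
    n: int,
    tile_size: int,
    output_downsample: float,
    seed: int,
    out_dir: str | Path,
) -> tuple[list[Path], Path]:
    """Extract n tiles from uniformly random positions (no masking).

    Top-left native coordinates are drawn uniformly from
    ``[0, W - tile_size*d] x [0, H - tile_size*d]`` with a seeded RNG;
    the manifest records coordinates and the seed.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    w0, h0 = slide.dimensions
    xs, ys = random_tile_origins(w0, h0, tile_size, output_downsample, n, seed)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = slide.path.stem
    written: list[Path] = []
    for i, (x, y) in enumerate(zip(xs.tolist(), ys.tolist())):
        tile = _read_padded_tile(slide, x, y, tile_size, output_downsample)
        path = out_dir / f"{stem}_random_{i:05d}.png"
        Image.fromarray(tile, mode="RGB").save(path)
        written.append(path)

    manifest_path = out_dir / f"{stem}_random_manifest.tsv"
    pd.DataFrame(
        {
            "slide": stem,
            "index": np.arange(n),
            "x": xs,
            "y": ys,
            "width": tile_size,
            "height": tile_size,
            "seed": seed,
        }
    ).to_csv(manifest_path, sep="\t", index=False)
    return written, manifest_path
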