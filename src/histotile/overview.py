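"""Segmentation-overview rendering and run metadata.

The overview is the visual QC artifact of a run: the slide rendered at
its own downsample with the tile grid drawn as 1-pixel pure-red lines
and each selected tile marked with a pure-blue cross (both diagonals of
its footprint).  The run log is a JSON sidecar echoing every parameter
plus summary counts so a run can be audited or reproduced.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from skimage.draw import line as draw_line

from . import slide_io
from .errors import ParameterError
from .tiler import GridSpec, TileRecord

__all__ = ["render_overview", "write_run_log", "RED", "BLUE"]

RED = (255, 0, 0)
BLUE = (0, 0, 255)


def render_overview(
    slide: slide_io.SlideHandle,
    records: list[TileRecord],
    grid: GridSpec,
    overview_downsample: float,
) -> np.ndarray:
    """Render the slide with the red grid and blue selected-tile crosses."""
    if overview_downsample < 1:
        raise ParameterError(f"overview_downsample must be >= 1, got {overview_downsample}")
    base = slide_io.read_full(slide, overview_downsample).copy()
    h, w = base.shape[:2]
    s = grid.native_span / overview_downsample  # tile side at overview scale

    for col in range(grid.n_cols + 1):
        x = int(round(col * s))
        if 0 <= x < w:
            base[:, x] = RED
    for row in range(grid.n_rows + 1):
        y = int(round(row * s))
        if 0 <= y < h:
            base[y, :] = RED

    for rec in records:
        if not rec.selected:
            continue
        x0 = int(round(rec.col * s))
        x1 = min(int(round((rec.col + 1) * s)), w) - 1
        y0 = int(round(rec.row * s))
        y1 = min(int(round((rec.row + 1) * s)), h) - 1
        if x1 <= x0 or y1 <= y0:
            continue
        for (ya, xa), (yb, xb) in (((y0, x0), (y1, x1)), ((y1, x0), (y0, x1))):
            rr, cc = draw_line(ya, xa, yb, xb)
            base[rr, cc] = BLUE
    return base


def write_run_log(config: dict, summary: dict, path: str | Path) -> Path:
    """Write a JSON sidecar with the full configuration and run summary."""
    path = Path(path)
    payload = {
        "config": config,
        "summary": summary,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
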