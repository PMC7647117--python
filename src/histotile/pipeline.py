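"""End-to-end pipeline orchestration.

A run is: open the slide, build the tissue mask at ``mask_downsample``
(graph / otsu / adaptive), lay the tile grid at ``output_downsample``,
score and select tiles against the ``content_threshold``, extract the
selected tiles (skipped in test mode), render the overview, and write
the run log.  ``random`` mode bypasses masking entirely and extracts
tiles from seeded uniform positions.

On any stage failure, files written so far in this run are removed and
a PipelineError naming the stage is raised.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from PIL import Image

from . import __version__, slide_io, tiler
from .edge_ops import CannyParams
from .errors import ConfigError, HistotileError, PipelineError
from .graph_seg import SegParams
from .mask_methods import ExclusionSpec, MaskParams, default_min_size, make_mask
from .overview import render_overview, write_run_log
from .tiler import GridSpec

__all__ = ["PipelineConfig", "RunResult", "run_pipeline"]

logger = logging.getLogger(__name__)

METHODS = ("graph", "otsu", "adaptive", "random")


@dataclass
class PipelineConfig:
    """Every user-settable parameter of one run.

    The graph method is the default; thresholds and factors mirror the
    library defaults (tile 256 at native output resolution, mask and
    overview at 1/16, 5% tissue content, all four borders excluded).
    ``seg_min_size = 0`` means "derive from the tile footprint" (half a
    tile's area at mask resolution).
    """

    input: str = ""
    output: str = "output"
    method: str = "graph"
    tile_size: int = 256
    output_downsample: float = 1.0
    mask_downsample: float = 16.0
    overview_downsample: float = 16.0
    content_threshold: float = 0.05
    keep_all: bool = False
    borders: tuple[bool, bool, bool, bool] = (True, True, True, True)
    corners: tuple[bool, bool, bool, bool] = (False, False, False, False)
    margin: int = 1
    seg_k: float = 10000.0
    seg_min_size: int = 0
    seg_sigma: float = 0.0
    canny_sigma: float = 1.4
    canny_low: float = 0.1
    canny_high: float = 0.2
    adaptive_block_size: int = 51
    adaptive_offset: float = 8.0
    n_random: int = 100
    seed: int = 42
    test_mode: bool = False
    save_overview: bool = True

    def validate(self) -> None:
        if not self.input:
            raise ConfigError("no input slide given")
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}, got {self.method!r}")
        if min(self.output_downsample, self.mask_downsample, self.overview_downsample) < 1:
            raise ConfigError("downsample factors must be >= 1")
        if not 0 <= self.content_threshold <= 1:
            raise ConfigError("content_threshold must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["borders"] = list(self.borders)
        d["corners"] = list(self.corners)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        kwargs["borders"] = tuple(kwargs["borders"])
        kwargs["corners"] = tuple(kwargs["corners"])
        return cls(**kwargs)

    def mask_params(self) -> MaskParams:
        min_size = self.seg_min_size or default_min_size(
            self.tile_size, self.output_downsample, self.mask_downsample
        )
        return MaskParams(
            canny=CannyParams(sigma=self.canny_sigma, low=self.canny_low, high=self.canny_high),
            seg=SegParams(k=self.seg_k, min_size=min_size, sigma=self.seg_sigma),
            block_size=self.adaptive_block_size,
            offset=self.adaptive_offset,
        )


@dataclass
class RunResult:
    """Outputs and counts of a completed run."""

    config: PipelineConfig
    grid_tiles: int = 0
    selected_tiles: int = 0
    tiles_written: int = 0
    records: list = field(default_factory=list)
    manifest_path: Path | None = None
    overview_path: Path | None = None
    log_path: Path | None = None


class _Tracker:
    """Record files created in this run so failures can clean up."""

    def __init__(self) -> None:
        self.created: list[Path] = []

    def add(self, *paths: Path | None) -> None:
        self.created.extend(p for p in paths if p is not None)

    def cleanup(self) -> None:
        for p in self.created:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute one full run; see module docstring for the stage order."""
    config.validate()
    out_dir = Path(config.output)
    out_dir.mkdir(parents=True, exist_ok=True)
    track = _Tracker()
    result = RunResult(config=config)
    stage = "open_slide"
    t0 = time.perf_counter()
    try:
        slide = slide_io.open_slide(config.input)
        w0, h0 = slide.dimensions
        logger.info("opened %s: %d x %d px, %d levels", slide.path.name, w0, h0, slide.level_count)

        if config.method == "random":
            stage = "random_sampling"
            written, manifest = tiler.sample_random_tiles(
                slide,
                config.n_random,
                config.tile_size,
                config.output_downsample,
                config.seed,
                out_dir,
            )
            track.add(manifest, *written)
            result.tiles_written = len(written)
            result.manifest_path = manifest
        else:
            stage = "mask"
            excl = ExclusionSpec(
                borders=config.borders, corners=config.corners, margin=config.margin
            )
            mask = make_mask(
                slide, config.method, config.mask_downsample, config.mask_params(), excl
            )
            logger.info("mask foreground fraction: %.4f", mask.foreground_fraction)

            stage = "grid"
            grid = GridSpec(
                native_w=w0,
                native_h=h0,
                tile_size=config.tile_size,
                output_downsample=config.output_downsample,
                mask_downsample=config.mask_downsample,
                content_threshold=config.content_threshold,
                keep_all=config.keep_all,
            )
            records = tiler.compute_tile_grid(w0, h0, grid)
            records = tiler.score_tiles(records, mask, grid)
            records = tiler.select_tiles(records, config.content_threshold, config.keep_all)
            result.records = records
            result.grid_tiles = len(records)
            result.selected_tiles = sum(r.selected for r in records)
            logger.info(
                "grid %d x %d: %d / %d tiles selected",
                grid.n_rows,
                grid.n_cols,
                result.selected_tiles,
                result.grid_tiles,
            )

            if config.test_mode:
                stage = "manifest"
                manifest = out_dir / f"{slide.path.stem}_manifest.tsv"
                tiler._manifest_frame(slide.path.stem, records).to_csv(
                    manifest, sep="\t", index=False
                )
                track.add(manifest)
                result.manifest_path = manifest
            else:
                stage = "extract"
                written, manifest = tiler.extract_tiles(slide, records, grid, out_dir)
                track.add(manifest, *written)
                result.tiles_written = len(written)
                result.manifest_path = manifest

            if config.save_overview:
                stage = "overview"
                img = render_overview(slide, records, grid, config.overview_downsample)
                result.overview_path = out_dir / f"{slide.path.stem}_overview.png"
                Image.fromarray(img, mode="RGB").save(result.overview_path)
                track.add(result.overview_path)

        stage = "run_log"
        summary = {
            "slide": slide.path.name,
            "native_width": w0,
            "native_height": h0,
            "level_count": slide.level_count,
            "grid_tiles": result.grid_tiles,
            "selected_tiles": result.selected_tiles,
            "tiles_written": result.tiles_written,
            "method": config.method,
            "seed": config.seed,
            "version": __version__,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        result.log_path = write_run_log(
            config.to_dict(), summary, out_dir / f"{slide.path.stem}_log.json"
        )
        return result
    except HistotileError as exc:
        track.cleanup()
        raise PipelineError(stage, str(exc)) from exc
    except Exception as exc:  # pragma: no cover - unexpected failure path
        track.cleanup()
        raise PipelineError(stage, f"unexpected error: {exc}") from exc
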