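"""Binary tissue-mask generation.

Three routes from a slide region to a foreground mask:

``graph``     Canny edge map -> graph-based segmentation -> components
              touching the slide border (or user-chosen exclusion strips
              and corner squares) are declared background, everything
              else tissue.  Robust on slides with heterogeneous stain.
``otsu``      Global threshold maximizing between-class variance of the
              gray histogram; tissue is the dark side (H&E on white).
``adaptive``  Per-pixel threshold from the local window mean minus an
              offset; picks up tissue against local background even
              under uneven illumination, at the cost of hollowing out
              large homogeneous regions.

Masks carry the downsample factor they were computed at, so the tiler
can map tile footprints onto them regardless of output resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import edge_ops, graph_seg, slide_io
from .edge_ops import CannyParams
from .errors import ParameterError
from .graph_seg import LabelMap, SegParams

__all__ = [
    "BinaryMask",
    "ExclusionSpec",
    "MaskParams",
    "classify_background",
    "otsu_threshold",
    "adaptive_mask",
    "make_mask",
    "default_min_size",
]

# Minimum between-class contrast (gray levels) for the Otsu split to be
# trusted as tissue vs background.  Stained tissue on a bright slide
# separates by tens of gray levels; an optimum whose class means sit
# within ~10 levels of each other is splitting sensor noise or
# quantization, and the slide is treated as having no tissue.
OTSU_MIN_CONTRAST = 10.0


@dataclass
class BinaryMask:
    """Foreground raster plus the downsample it was computed at."""

    fg: np.ndarray
    downsample: float

    @property
    def width(self) -> int:
        return self.fg.shape[1]

    @property
    def height(self) -> int:
        return self.fg.shape[0]

    @property
    def foreground_fraction(self) -> float:
        return float(self.fg.mean())


@dataclass(frozen=True)
class ExclusionSpec:
    """Border strips / corner squares whose components count as background.

    ``borders`` is (top, right, bottom, left); ``corners`` is
    (top-left, top-right, bottom-right, bottom-left); ``margin`` is the
    strip width / corner-square side in mask pixels.  With no flag set,
    classification falls back to "largest component is background".
    """

    borders: tuple[bool, bool, bool, bool] = (True, True, True, True)
    corners: tuple[bool, bool, bool, bool] = (False, False, False, False)
    margin: int = 1

    @property
    def any_active(self) -> bool:
        return any(self.borders) or any(self.corners)

    def validate(self) -> None:
        if self.any_active and self.margin < 1:
            raise ParameterError("margin must be >= 1 when any border/corner flag is set")


@dataclass(frozen=True)
class MaskParams:
    """Method parameters bundled for make_mask.

    ``seg = None`` derives the segmentation parameters at mask time:
    k = 10000 and min_size = half a 256-px native-resolution tile's area
    at the mask downsample, which suppresses speckle components smaller
    than half a tile.
    """

    canny: CannyParams = field(default_factory=CannyParams)
    seg: SegParams | None = None
    block_size: int = 51
    offset: float = 8.0


def default_min_size(tile_size: int, output_downsample: float, mask_downsample: float) -> int:
    """Half a tile's area at mask resolution: speckle below this merges away."""
    side = tile_size * output_downsample / mask_downsample
    return max(1, int(round(side * side / 2.0)))


def classify_background(labels: LabelMap, excl: ExclusionSpec, downsample: float = 1.0) -> BinaryMask:
    """Mark components touching active exclusion regions as background.

    Every component with at least one pixel inside an active border
    strip or corner square (side = margin) becomes background; the rest
    is foreground.  With no active region the single largest component
    is background (ties broken toward the smaller label).
    """
    excl.validate()
    lab = labels.labels
    h, w = lab.shape
    if excl.any_active and (excl.margin > h or excl.margin > w):
        raise ParameterError(f"margin {excl.margin} exceeds mask dimensions {w} x {h}")

    if not excl.any_active:
        counts = np.bincount(lab.ravel())
        bg_ids = np.array([int(np.argmax(counts))])
    else:
        m = excl.margin
        region = np.zeros((h, w), dtype=bool)
        top, right, bottom, left = excl.borders
        if top:
            region[:m, :] = True
        if bottom:
            region[-m:, :] = True
        if left:
            region[:, :m] = True
        if right:
            region[:, -m:] = True
        tl, tr, br, bl = excl.corners
        if tl:
            region[:m, :m] = True
        if tr:
            region[:m, -m:] = True
        if br:
            region[-m:, -m:] = True
        if bl:
            region[-m:, :m] = True
        bg_ids = np.unique(lab[region])

    fg = ~np.isin(lab, bg_ids)
    return BinaryMask(fg=fg, downsample=downsample)


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's global threshold on the 256-bin histogram.

    Returns the smallest t in [0, 255] maximizing the between-class
    variance ``w0 * w1 * (mu0 - mu1)^2`` of the split ``value < t`` vs
    ``value >= t``.  A constant image (zero variance everywhere) returns
    the constant itself, under which everything is background.
    """
    if img.size == 0:
        raise ParameterError("image is empty")
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    # cum0[t] = #pixels < t ; csum[t] = sum of values < t, for t = 0..255
    cum0 = np.concatenate(([0.0], np.cumsum(hist)))[:256]
    csum = np.concatenate(([0.0], np.cumsum(hist * np.arange(256))))[:256]
    w0 = cum0 / n
    w1 = 1.0 - w0
    total = csum[-1] + hist[255] * 255  # sum of all values
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(cum0 > 0, csum / cum0, 0.0)
        mu1 = np.where(n - cum0 > 0, (total - csum) / (n - cum0), 0.0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    if sigma_b.max() == 0:
        return int(img.min())
    return int(np.argmax(sigma_b))


def otsu_class_contrast(img: np.ndarray, t: int) -> float:
    """Distance between the class means of the split ``value < t``.

    Zero for a degenerate split (one class empty)."""
    v = img.astype(np.float64).ravel()
    fg = v < t
    if not fg.any() or fg.all():
        return 0.0
    return float(v[~fg].mean() - v[fg].mean())


def adaptive_mask(
    img: np.ndarray, block_size: int, offset: float, downsample: float = 1.0
) -> BinaryMask:
    """Foreground where value < (local mean over block) - offset.

    The local mean uses a ``block_size`` square window with reflective
    borders; ``block_size`` must be odd and >= 3.
    """
    if block_size < 3 or block_size % 2 == 0:
        raise ParameterError(f"block_size must be odd and >= 3, got {block_size}")
    mean = ndimage.uniform_filter(img.astype(np.float64), size=block_size, mode="reflect")
    return BinaryMask(fg=img < (mean - offset), downsample=downsample)


def make_mask(
    slide: slide_io.SlideHandle,
    method: str,
    mask_downsample: float,
    params: MaskParams | None = None,
    excl: ExclusionSpec | None = None,
) -> BinaryMask:
    """Compute a tissue mask for the whole slide at ``mask_downsample``.

    ``graph``: grayscale -> Canny -> graph segmentation of the edge map
    -> border/corner background classification.  ``otsu`` / ``adaptive``:
    grayscale -> the corresponding threshold rule (no background
    classification step).
    """
    if params is None:
        params = MaskParams()
    if excl is None:
        excl = ExclusionSpec()
    region = slide_io.read_full(slide, mask_downsample)
    gray = edge_ops.to_grayscale(region)

    if method == "graph":
        seg = params.seg or SegParams(
            k=10000.0, min_size=default_min_size(256, 1.0, mask_downsample)
        )
        edges = edge_ops.canny(gray, params.canny)
        # The NMS skeleton is one pixel wide, so an 8-connected grid graph
        # could hop it diagonally with a weight-0 edge and flood enclosed
        # tissue with background; a one-pixel dilation closes that route.
        edges = ndimage.binary_dilation(edges, structure=np.ones((3, 3), dtype=bool))
        labels = graph_seg.segment_image(edges, seg)
        return classify_background(labels, excl, downsample=mask_downsample)
    if method == "otsu":
        t = otsu_threshold(gray)
        if otsu_class_contrast(gray, t) < OTSU_MIN_CONTRAST:
            fg = np.zeros(gray.shape, dtype=bool)
        else:
            fg = gray < t
        return BinaryMask(fg=fg, downsample=mask_downsample)
    if method == "adaptive":
        return adaptive_mask(gray, params.block_size, params.offset, downsample=mask_downsample)
    raise ParameterError(f"unknown mask method: {method!r}")
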