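"""Grayscale conversion, Gaussian smoothing, and Canny edge detection.

The graph-based masking method does not segment the slide directly: it
first computes a Canny edge image, which suppresses stain texture and
leaves the tissue/background boundaries, and the segmenter then operates
on that binary edge raster.  The detector here is the classic pipeline —
Gaussian smoothing, Sobel gradients, non-maximum suppression quantized
to four directions, and two-threshold hysteresis with 8-connectivity —
implemented over float arrays so no precision is lost between stages.

Grayscale uses BT.601 luminance weights (0.299, 0.587, 0.114).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError

__all__ = ["CannyParams", "to_grayscale", "gaussian_smooth", "canny", "edge_map_to_gray"]

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class CannyParams:
    """Canny detector parameters.

    ``sigma`` is the smoothing spread in pixels of the image the detector
    runs on (the mask-resolution raster in the pipeline).  ``low`` and
    ``high`` are hysteresis thresholds on gradient magnitude; with
    ``relative=True`` (the default) they are fractions of the per-image
    maximum gradient magnitude, which makes one setting usable across
    slides of very different stain intensity.
    """

    sigma: float = 1.4
    low: float = 0.1
    high: float = 0.2
    relative: bool = True

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        if not 0 <= self.low <= self.high:
            raise ParameterError(f"need 0 <= low <= high, got low={self.low}, high={self.high}")


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance of an (h, w, 3) uint8 image, rounded half-up."""
    y = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    return np.floor(y + 0.5).clip(0, 255).astype(np.uint8)


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Normalized 1-D Gaussian truncated at 4*sigma."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    radius = int(math.ceil(4.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return k / k.sum()


def _smooth_float(img: np.ndarray, sigma: float) -> np.ndarray:
    k = gaussian_kernel(sigma)
    out = ndimage.correlate1d(img.astype(np.float64), k, axis=0, mode="reflect")
    return ndimage.correlate1d(out, k, axis=1, mode="reflect")


def gaussian_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur of a uint8 gray image (reflective borders)."""
    return np.floor(_smooth_float(img, sigma) + 0.5).clip(0, 255).astype(np.uint8)


def _nms(mag: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Non-maximum suppression with orientation quantized to 4 directions.

    Plateau ties are broken by requiring a strict maximum against the
    second neighbor only, so a two-pixel-wide ridge keeps exactly one
    pixel — this is what makes an ideal step edge one pixel wide.
    """
    h, w = mag.shape
    # Pad with zeros so border pixels compare against empty neighbors.
    p = np.zeros((h + 2, w + 2), dtype=mag.dtype)
    p[1:-1, 1:-1] = mag

    angle = np.degrees(np.arctan2(gy, gx)) % 180.0
    bin0 = (angle < 22.5) | (angle >= 157.5)           # gradient ~horizontal
    bin1 = (angle >= 22.5) & (angle < 67.5)            # ~45 deg
    bin2 = (angle >= 67.5) & (angle < 112.5)           # ~vertical
    bin3 = (angle >= 112.5) & (angle < 157.5)          # ~135 deg

    c = p[1:-1, 1:-1]

    def neigh(dy: int, dx: int) -> np.ndarray:
        return p[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]

    # Raster convention: y grows downward, so a 45-degree gradient points
    # toward (dx=+1, dy=+1) and its across-edge neighbors are the main
    # diagonal; 135 degrees uses the anti-diagonal.
    keep = np.zeros((h, w), dtype=bool)
    for b, (n1, n2) in (
        (bin0, (neigh(0, -1), neigh(0, 1))),
        (bin1, (neigh(-1, -1), neigh(1, 1))),
        (bin2, (neigh(-1, 0), neigh(1, 0))),
        (bin3, (neigh(-1, 1), neigh(1, -1))),
    ):
        keep |= b & (c >= n1) & (c > n2)
    return keep & (mag > 0)


def canny(img: np.ndarray, params: CannyParams | None = None) -> np.ndarray:
    """Edge map (boolean, same shape) of a uint8 gray image."""
    if params is None:
        params = CannyParams()
    params.validate()

    sm = _smooth_float(img, params.sigma)
    gx = ndimage.correlate(sm, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(sm, _SOBEL_Y, mode="reflect")
    mag = np.hypot(gx, gy)
    mmax = mag.max()
    # Sub-1e-6 magnitudes are convolution round-off on a flat image, not
    # gradients; without this floor the relative thresholds would rescale
    # numerical dust into "edges".
    if mmax < 1e-6:
        return np.zeros(img.shape, dtype=bool)

    low = params.low * mmax if params.relative else params.low
    high = params.high * mmax if params.relative else params.high

    ridge = _nms(mag, gx, gy)
    cand = ridge & (mag >= low) & (mag > 0)
    strong = cand & (mag >= high)
    if not strong.any():
        return np.zeros(img.shape, dtype=bool)

    labels, _n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    keep_ids = np.unique(labels[strong])
    return np.isin(labels, keep_ids) & cand


def edge_map_to_gray(edges: np.ndarray) -> np.ndarray:
    """Render a boolean edge map as uint8 {edge: 255, non-edge: 0}."""
    return edges.astype(np.uint8) * 255
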