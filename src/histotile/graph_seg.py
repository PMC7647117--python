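"""Efficient graph-based segmentation (Felzenszwalb–Huttenlocher).

The image is an 8-connected grid graph whose edge weights are absolute
intensity differences.  Edges are processed in non-decreasing weight
order; two components C1, C2 merge iff

    w <= min(Int(C1) + k/|C1|, Int(C2) + k/|C2|)

where Int(C) is the largest weight of an edge that previously merged
pixels inside C (0 for singletons) and k is the scale constant of the
threshold function tau(C) = k/|C|: larger k tolerates more internal
variation and yields coarser partitions.  A second pass over the same
sorted edge list then merges away any component smaller than
``min_size``.  Equal-weight edges are ordered by (weight, a, b), which
makes the whole procedure deterministic and lets an exact brute-force
oracle reproduce it.

In the masking pipeline the input is the Canny edge map rendered as
{edge: 255, non-edge: 0}: uniform regions (background, blob interiors)
coalesce over weight-0 edges first, and the weight-255 edges crossing
the drawn boundaries then fail the merge criterion, so tissue regions
enclosed by edges become separate components.

The two merge passes run under numba; the union-find bookkeeping is the
standard parent/size/threshold triple with path halving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ParameterError, StructuralError

__all__ = ["SegParams", "EdgeList", "LabelMap", "build_grid_graph", "segment_graph", "segment_image"]


@dataclass(frozen=True)
class SegParams:
    """k: threshold-function scale; min_size: post-merge floor; sigma: pre-smoothing."""

    k: float = 10000.0
    min_size: int = 1
    sigma: float = 0.0

    def validate(self) -> None:
        if self.k <= 0:
            raise ParameterError(f"k must be positive, got {self.k}")
        if self.min_size < 1:
            raise ParameterError(f"min_size must be >= 1, got {self.min_size}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")


@dataclass
class EdgeList:
    """Weighted undirected edges as parallel arrays (a < rows of b not implied)."""

    a: np.ndarray
    b: np.ndarray
    w: np.ndarray

    def __len__(self) -> int:
        return len(self.a)


@dataclass
class LabelMap:
    """Per-pixel component ids, compacted to 0..n-1 by first-pixel order."""

    labels: np.ndarray

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def n_components(self) -> int:
        return int(self.labels.max()) + 1


def build_grid_graph(img: np.ndarray) -> EdgeList:
    """8-connected grid graph; weight = |intensity difference| of endpoints.

    Each undirected neighbor pair appears exactly once.  Pixel indices
    are row-major (``idx = y * width + x``).
    """
    if img.size == 0:
        raise ParameterError("image is empty")
    h, w = img.shape
    v = img.astype(np.int64)
    idx = np.arange(h * w, dtype=np.int64).reshape(h, w)

    pairs = []
    # (dy, dx): right, down, down-right, down-left
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        if dx >= 0:
            a = idx[: h - dy if dy else h, : w - dx if dx else w]
            b = idx[dy:, dx:]
            wa = v[: a.shape[0], : a.shape[1]]
            wb = v[dy:, dx:]
        else:
            a = idx[: h - dy, -dx:]
            b = idx[dy:, :dx]
            wa = v[: h - dy, -dx:]
            wb = v[dy:, :dx]
        pairs.append((a.ravel(), b.ravel(), np.abs(wa - wb).ravel()))

    a = np.concatenate([p[0] for p in pairs])
    b = np.concatenate([p[1] for p in pairs])
    wt = np.concatenate([p[2] for p in pairs]).astype(np.float64)
    return EdgeList(a=a, b=b, w=wt)


@njit(cache=False)
def _find(parent: np.ndarray, i: int) -> int:
    while parent[i] != i:
        parent[i] = parent[parent[i]]  # path halving
        i = parent[i]
    return i


@njit(cache=False)
def _merge_passes(
    order: np.ndarray,
    ea: np.ndarray,
    eb: np.ndarray,
    ew: np.ndarray,
    n: int,
    k: float,
    min_size: int,
) -> np.ndarray:
    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)
    # threshold[root] = Int(C) + k/|C|; Int starts at 0 for singletons
    thr = np.full(n, k, dtype=np.float64)

    for t in range(order.shape[0]):
        e = order[t]
        ra = _find(parent, ea[e])
        rb = _find(parent, eb[e])
        if ra == rb:
            continue
        w = ew[e]
        if w <= thr[ra] and w <= thr[rb]:
            if size[ra] < size[rb]:
                ra, rb = rb, ra
            parent[rb] = ra
            size[ra] += size[rb]
            thr[ra] = w + k / size[ra]

    for t in range(order.shape[0]):
        e = order[t]
        ra = _find(parent, ea[e])
        rb = _find(parent, eb[e])
        if ra == rb:
            continue
        if size[ra] < min_size or size[rb] < min_size:
            if size[ra] < size[rb]:
                ra, rb = rb, ra
            parent[rb] = ra
            size[ra] += size[rb]

    roots = np.empty(n, dtype=np.int64)
    for i in range(n):
        roots[i] = _find(parent, i)
    return roots


def _compact_first_occurrence(roots: np.ndarray) -> np.ndarray:
    uniq, first, inv = np.unique(roots, return_index=True, return_inverse=True)
    rank = np.empty(len(uniq), dtype=np.int64)
    rank[np.argsort(first, kind="stable")] = np.arange(len(uniq))
    return rank[inv]


def segment_graph(edges: EdgeList, n_vertices: int, params: SegParams, shape: tuple[int, int]) -> LabelMap:
    """Run the sorted-edge merge criterion and min_size pass; compact labels."""
    params.validate()
    if len(edges) and (edges.a.max() >= n_vertices or edges.b.max() >= n_vertices):
        raise StructuralError("edge references a vertex index out of range")
    if len(edges) and (edges.a.min() < 0 or edges.b.min() < 0):
        raise StructuralError("edge references a negative vertex index")
    order = np.lexsort((edges.b, edges.a, edges.w)).astype(np.int64)
    roots = _merge_passes(
        order, edges.a, edges.b, edges.w, n_vertices, float(params.k), int(params.min_size)
    )
    labels = _compact_first_occurrence(roots)
    return LabelMap(labels=labels.reshape(shape))


def segment_image(img: np.ndarray, params: SegParams | None = None) -> LabelMap:
    """Segment a uint8 gray image (or boolean edge map rendered as 0/255).

    Optional Gaussian pre-smoothing (``params.sigma > 0``), then grid
    graph construction and the two merge passes.
    """
    if params is None:
        params = SegParams()
    params.validate()
    if img.dtype == bool:
        img = img.astype(np.uint8) * 255
    if params.sigma > 0:
        from .edge_ops import gaussian_smooth

        img = gaussian_smooth(img, params.sigma)
    edges = build_grid_graph(img)
    return segment_graph(edges, img.size, params, img.shape)
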