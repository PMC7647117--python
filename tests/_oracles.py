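"""Independent brute-force oracles for the segmentation and Otsu tests.

These deliberately avoid the package's data structures and optimizations:
the segmentation oracle keeps explicit pixel sets (no union-find) and
applies the merge criterion literally; the Otsu oracle scans all 256
thresholds with scalar arithmetic.
"""

from __future__ import annotations

import numpy as np


def fh_segment_oracle(img: np.ndarray, k: float, min_size: int) -> np.ndarray:
    """Literal graph-merge segmentation of a small gray image.

    8-connected grid; edges sorted by (weight, a, b); components C1, C2
    merge iff w <= min(Int(C1) + k/|C1|, Int(C2) + k/|C2|); a second pass
    in the same order merges components below min_size.  Labels are
    compacted by first-pixel order.  O(n^2)-ish: tiny images only.
    """
    h, w = img.shape
    n = h * w
    edges = []
    for y in range(h):
        for x in range(w):
            a = y * w + x
            for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    b = yy * w + xx
                    edges.append((abs(int(img[y, x]) - int(img[yy, xx])), a, b))
    edges.sort()

    member = list(range(n))              # pixel -> component id
    comps = {i: {i} for i in range(n)}   # component id -> pixel set
    internal = {i: 0.0 for i in range(n)}

    def merge(ca: int, cb: int, wgt: float | None) -> None:
        if len(comps[ca]) < len(comps[cb]):
            ca, cb = cb, ca
        for p in comps[cb]:
            member[p] = ca
        comps[ca] |= comps.pop(cb)
        if wgt is not None:
            internal[ca] = wgt
        internal.pop(cb, None)

    for wgt, a, b in edges:
        ca, cb = member[a], member[b]
        if ca == cb:
            continue
        if wgt <= internal[ca] + k / len(comps[ca]) and wgt <= internal[cb] + k / len(comps[cb]):
            merge(ca, cb, float(wgt))

    for wgt, a, b in edges:
        ca, cb = member[a], member[b]
        if ca == cb:
            continue
        if len(comps[ca]) < min_size or len(comps[cb]) < min_size:
            merge(ca, cb, None)

    labels = np.empty(n, dtype=np.int64)
    next_label = 0
    seen: dict[int, int] = {}
    for p in range(n):
        c = member[p]
        if c not in seen:
            seen[c] = next_label
            next_label += 1
        labels[p] = seen[c]
    return labels.reshape(h, w)


def otsu_oracle(img: np.ndarray) -> int:
    """Exhaustive between-class-variance search over t = 0..255."""
    hist = np.bincount(np.asarray(img).ravel(), minlength=256)
    n = int(hist.sum())
    best_t, best_var = 0, -1.0
    for t in range(256):
        n0 = int(hist[:t].sum())
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            var = 0.0
        else:
            mu0 = float((hist[:t] * np.arange(t)).sum()) / n0
            mu1 = float((hist[t:] * np.arange(t, 256)).sum()) / n1
            var = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
        if var > best_var:
            best_t, best_var = t, var
    if best_var == 0.0:
        vals = np.nonzero(hist)[0]
        return int(vals[0]) if len(vals) else 0
    return best_t
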