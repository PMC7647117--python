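"""Shared fixtures: synthetic slides at two scales.

``small_slide`` is a quick 1024 px fixture for unit tests; ``study_slides``
are the ten full-scale (4096 px, three pyramid levels, five blobs) slides
that the end-to-end selection checks run against.  Both are generated
once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from histotile import SyntheticSlideSpec, generate_synthetic_slide


def truth_at(truth: np.ndarray, factor: int) -> np.ndarray:
    """Ground-truth mask box-downsampled to a mask resolution (majority rule)."""
    h = (truth.shape[0] // factor) * factor
    w = (truth.shape[1] // factor) * factor
    t = truth[:h, :w].reshape(h // factor, factor, w // factor, factor)
    return t.mean(axis=(1, 3)) >= 0.5


@pytest.fixture(scope="session")
def small_slide(tmp_path_factory):
    """1024 px two-blob slide: (path, ground-truth mask)."""
    spec = SyntheticSlideSpec(
        width=1024, height=1024, n_blobs=2, blob_radius_range=(80, 140), levels=(1, 4, 16), seed=3
    )
    out = tmp_path_factory.mktemp("small_slide")
    path, truth = generate_synthetic_slide(spec, out, stem="small")
    return path, truth


@pytest.fixture(scope="session")
def blank_slide(tmp_path_factory):
    """1024 px slide with no blobs (noise-only background)."""
    spec = SyntheticSlideSpec(
        width=1024, height=1024, n_blobs=0, levels=(1, 4, 16), seed=11
    )
    out = tmp_path_factory.mktemp("blank_slide")
    path, truth = generate_synthetic_slide(spec, out, stem="blank")
    return path, truth


@pytest.fixture(scope="session")
def study_slides(tmp_path_factory):
    """Ten seeded full-scale fixture slides: list of (path, ground truth)."""
    out = tmp_path_factory.mktemp("study_slides")
    slides = []
    for seed in range(10):
        path, truth = generate_synthetic_slide(
            SyntheticSlideSpec(seed=seed), out, stem=f"study{seed}"
        )
        slides.append((path, truth))
    return slides
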