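"""Shared fixtures: random mask generation and a small phantom cohort."""

from __future__ import annotations

import numpy as np
import pytest

from endoseg.phantom import generate_cohort

COHORT_RANGES = {"target_thickness_px": (5, 40), "curvature": (0.0, 1.0)}


def random_blob_mask(rng: np.random.Generator, max_side: int = 64) -> np.ndarray:
    """A random binary mask: thresholded smoothed noise, possibly multi-blob."""
    from scipy import ndimage

    h = int(rng.integers(3, max_side + 1))
    w = int(rng.integers(3, max_side + 1))
    noise = rng.random((h, w))
    smoothed = ndimage.uniform_filter(noise, size=int(rng.integers(1, 6)))
    mask = smoothed > rng.uniform(0.35, 0.65)
    if not mask.any():
        mask[h // 2, w // 2] = True
    return mask


@pytest.fixture(scope="session")
def small_cohort():
    """Eight phantoms spanning the thickness range; session-cached."""
    return generate_cohort(8, COHORT_RANGES, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
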