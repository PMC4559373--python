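"""Shared fixtures: filter banks and synthetic descriptor sets.

Descriptor-space fixtures are Gaussian clouds with known class margins —
they exercise the boundary/design machinery without paying for image
synthesis and filtering.
"""

from __future__ import annotations

import numpy as np
import pytest

from percat.gist import gabor_bank


@pytest.fixture(scope="session")
def bank():
    """Default 4-scale x 8-orientation filter bank (expensive; share it)."""
    return gabor_bank()


def gaussian_descriptors(
    category_means: dict[str, np.ndarray],
    n_per_category: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    dim: int | None = None,
):
    """Labeled Gaussian descriptor cloud; returns (descriptors, categories)."""
    rng = np.random.default_rng(seed)
    if dim is None:
        dim = len(next(iter(category_means.values())))
    descriptors, categories = {}, {}
    for name, mean in category_means.items():
        mean = np.asarray(mean, float)
        assert mean.shape == (dim,)
        for k in range(n_per_category):
            img_id = f"{name}_{k:03d}"
            descriptors[img_id] = mean + noise_sd * rng.standard_normal(dim)
            categories[img_id] = name
    return descriptors, categories


def axis_mean(dim: int, axis: int, scale: float) -> np.ndarray:
    v = np.zeros(dim)
    v[axis] = scale
    return v
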