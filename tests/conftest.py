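"""Shared fixtures: cached synthetic samples and a trained endpoint model."""

from functools import lru_cache

import numpy as np
import pytest

import cctrace as ct


@lru_cache(maxsize=256)
def _sample(seed: int, sigma: float = 0.5) -> ct.SyntheticSample:
    return ct.generate_cc(ct.SyntheticSpec(seed=seed,
                                           boundary_noise_sigma_px=sigma))


@pytest.fixture(scope="session")
def gen():
    """Memoised synthetic-sample factory: gen(seed, sigma=0.5)."""
    return _sample


@pytest.fixture(scope="session")
def trained_model(gen):
    """Endpoint model trained on 15 synthetic masks (seeds 1000-1014)."""
    samples = [gen(s) for s in range(1000, 1015)]
    return ct.build_model([(s.mask, s.true_anterior, s.true_posterior)
                           for s in samples])


@pytest.fixture(scope="session")
def cc_sample(gen):
    """One default noisy synthetic callosum (seed 7)."""
    return gen(7)


def random_blob(seed: int, shape=(50, 50)) -> ct.BinaryMask:
    """Single-component, hole-free random blob for geometry tests."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, 4.0)
    fg = smooth > np.quantile(smooth, 0.75)
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), int))
    if n == 0:
        raise RuntimeError("empty blob")
    sizes = ndimage.sum(fg, labels, range(1, n + 1))
    fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return ct.BinaryMask(grid=fg.astype(np.uint8))
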