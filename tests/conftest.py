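"""Shared fixtures: tiny synthetic datasets and float64 gradient-check mode."""

from __future__ import annotations

import numpy as np
import pytest

from dendrofill import nn
from dendrofill import synthetic_data as sd
from dendrofill.preprocess import extract_segments, normalize_segment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def float64_nn():
    """Run nn layers in float64 on the pure-numpy path (for finite-difference
    gradient checks, where float32 rounding would swamp the comparison)."""
    old_dtype, old_numba = nn.DEFAULT_DTYPE, nn._HAS_NUMBA
    nn.DEFAULT_DTYPE = np.float64
    nn._HAS_NUMBA = False
    yield
    nn.DEFAULT_DTYPE = old_dtype
    nn._HAS_NUMBA = old_numba


@pytest.fixture(scope="session")
def small_dataset():
    """4 trees, 2 sites, 60 growing-season days, with missing-data gaps."""
    observed, clean, meta = sd.generate_dataset(
        n_trees=4, n_sites=2, n_hours=1440, seed=42, start="2020-06-01"
    )
    return observed, clean, meta


@pytest.fixture(scope="session")
def clean_segments(small_dataset):
    """Normalized complete 96-hour segments from the clean copies."""
    _, clean, _ = small_dataset
    segs = []
    for s in clean:
        segs.extend(normalize_segment(g) for g in extract_segments(s, 96))
    assert segs
    return segs


def numerical_gradient(f, x, eps=1e-6):
    """Central finite differences of scalar-valued f with respect to x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g
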