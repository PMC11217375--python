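"""Shared fixtures: small deterministic images and fields."""

import numpy as np
import pytest

from divcurlreg.fields import Volume, VectorField


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_field():
    """Factory for random vector fields of a given shape."""

    def make(shape=(10, 11, 12), seed=0, scale=1.0):
        r = np.random.default_rng(seed)
        return VectorField(scale * r.standard_normal((3, *shape)))

    return make


@pytest.fixture()
def random_volume():
    def make(shape=(10, 11, 12), seed=0):
        r = np.random.default_rng(seed)
        return Volume(r.random(shape))

    return make


def interior_window(shape, margin=4):
    """Smoothstep window: 1 deep inside, 0 within ``margin`` of any face."""
    parts = []
    for n in shape:
        x = np.arange(n, dtype=np.float64)
        w = np.clip(np.minimum(x, n - 1 - x) / max(margin, 1), 0.0, 1.0)
        parts.append(w**2 * (3 - 2 * w))
    return parts[0][:, None, None] * parts[1][None, :, None] * parts[2][None, None, :]


def hann_bump_field(n, margin=4, weights=(1.0, 0.7, -0.5)):
    """Smooth interior-supported product bump (Hann profile per axis)."""
    idx = np.arange(n, dtype=float)
    lo, hi = margin, n - 1 - margin
    s = np.clip((idx - lo) / (hi - lo), 0.0, 1.0)
    w = np.sin(np.pi * s) ** 2
    w[(idx < lo) | (idx > hi)] = 0.0
    W = w[:, None, None] * w[None, :, None] * w[None, None, :]
    return VectorField.from_components(*(c * W for c in weights))
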