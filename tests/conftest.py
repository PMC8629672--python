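"""Shared fixtures and independent oracles for the test suite."""
import math

import numpy as np
import pytest

from fwnnet import FWNNetParameters, NetworkConfig


def scalar_forward(x, params, config):
    """Naive loop-based re-implementation of the eight-layer forward pass.

    Deliberately written with plain Python floats and explicit loops, so it
    shares no code path with the vectorized implementation.
    """
    M, N, n = config.M, config.N_k, config.n
    num = 0.0
    den = 0.0
    for k in range(M):
        O = 1.0
        for j in range(n):
            u = (x[j] - params.c[k, j]) / params.sigma[k, j]
            O *= math.exp(-u * u)
        Y = params.ybar[k]
        for i in range(N):
            Psi = 1.0
            for j in range(n):
                a = params.a[k, i, j]
                z = (x[j] - params.b[k, i, j]) / a
                if config.wavelet_family == "mexican_hat":
                    v = (1.0 - z * z) * math.exp(-z * z / 2.0)
                else:
                    v = math.cos(5.0 * z) * math.exp(-z * z / 2.0)
                if config.normalize_wavelet:
                    v /= math.sqrt(abs(a))
                Psi *= v
            Y += params.w[k, i] * Psi
        num += O * Y
        den += O
    return num / den


def random_params(config, rng, spread=2.0):
    """Random parameter draw with widths and dilations kept well-scaled."""
    M, N, n = config.M, config.N_k, config.n
    return FWNNetParameters(
        c=rng.uniform(-spread, spread, (M, n)),
        sigma=rng.uniform(0.5, spread, (M, n)),
        b=rng.uniform(-spread, spread, (M, N, n)),
        a=rng.uniform(0.5, spread, (M, N, n)) * rng.choice([-1, 1], (M, N, n)),
        w=rng.uniform(-2, 2, (M, N)),
        ybar=rng.uniform(-2, 2, M),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return NetworkConfig(n=2, M=2, N_k=2, num_classes=4)
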