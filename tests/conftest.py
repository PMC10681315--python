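"""Shared fixtures: small random heterogeneous views and loop references."""

import numpy as np
import pytest

from hyperdrug.network import NetworkView


def random_view(rng, b=8, F=6, t=5, density=0.3, with_sides=True):
    """A random small heterogeneous network view for motif testing."""
    S = (rng.random((b, b)) < density).astype(np.int64)
    S = np.triu(S, 1)
    S = S + S.T
    Y = (rng.random((b, F)) < density).astype(np.int64)
    Z = (rng.random((F, F)) < density).astype(np.int64)
    np.fill_diagonal(Z, 0)
    W = G = V = None
    if with_sides:
        W = (rng.random((b, t)) < density).astype(np.int64)
        G = (rng.random((b, t)) < density).astype(np.int64)
        V = (rng.random((b, t)) < density).astype(np.int64)
    R = W if W is not None else S
    return NetworkView(S=S, Y=Y, Z=Z, W=W, G=G, V=V, R_train=R,
                       task_kind="DTI" if W is not None else "DDI")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_view(rng):
    return random_view(rng)
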