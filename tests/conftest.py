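import numpy as np
import pytest

from graphsurgery import WeightedNetwork, fixture, generate_er


@pytest.fixture
def triangle():
    return fixture("complete", 3)


@pytest.fixture
def path3():
    return fixture("path", 3)


@pytest.fixture
def cycle6():
    return fixture("cycle", 6)


@pytest.fixture
def k2():
    return fixture("complete", 2)


def random_connected(n: int, seed: int, extra_edges: int | None = None) -> WeightedNetwork:
    """Small random connected test graph (unit weights)."""
    if extra_edges is None:
        extra_edges = n  # mean degree ~ 2 + 2
    m = min(n - 1 + extra_edges, n * (n - 1) // 2)
    return generate_er(n, m, seed=seed)


def random_weighted(n: int, seed: int) -> WeightedNetwork:
    """Random connected graph with heterogeneous positive weights."""
    base = random_connected(n, seed)
    rng = np.random.default_rng(seed + 1)
    w = base.weights.copy()
    iu, ju = np.triu_indices(n, k=1)
    scale = rng.uniform(0.5, 2.0, size=len(iu))
    w[iu, ju] *= scale
    w[ju, iu] = w[iu, ju]
    return WeightedNetwork(w)
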