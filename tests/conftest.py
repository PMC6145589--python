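import numpy as np
import pytest

from planarnets.generators import GeneratorConfig, generate_mycelium_like, make_fixture
from planarnets.network import SpatialNetwork


@pytest.fixture
def square():
    """Unit square corners joined by the four sides."""
    return make_fixture("square")


@pytest.fixture
def path3():
    return make_fixture("path", 3)


@pytest.fixture
def grid3():
    return make_fixture("grid", 3)


@pytest.fixture(scope="session")
def mycelium_small():
    """One fixed mycelium-like network reused across read-only tests."""
    return generate_mycelium_like(GeneratorConfig(n_nodes=200, target_alpha=0.14, seed=11))


def random_connected_net(seed: int, n: int = 12) -> SpatialNetwork:
    """Random connected spatial graph: random tree plus a few extra edges."""
    rng = np.random.default_rng(seed)
    coords = rng.random((n, 2))
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    extra = rng.integers(0, n, size=(2 * n, 2))
    for u, v in extra:
        if u != v and len(edges) < 3 * n - 6:
            e = (min(int(u), int(v)), max(int(u), int(v)))
            if e not in edges:
                edges.append(e)
    return SpatialNetwork(
        node_ids=[f"n{i}" for i in range(n)],
        coords=coords,
        edges=np.array(edges, dtype=np.int64),
        name=f"rand-{seed}",
    )
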