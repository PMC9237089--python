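import networkx as nx
import numpy as np
import pytest

from orcci import Network, Partition, SideInfo


@pytest.fixture
def triangle() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def k4() -> Network:
    nodes = "abcd"
    return Network.from_edges(
        [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
    )


@pytest.fixture
def cycle4() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])


@pytest.fixture
def barbell() -> Network:
    """Two triangles {a,b,c} and {d,e,f} joined by the bridge c-d."""
    return Network.from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
    )


def random_network(n: int, p: float, seed: int) -> Network:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return Network.from_edges(
        ((f"v{u:02d}", f"v{v:02d}") for u, v in g.edges()),
        nodes=(f"v{i:02d}" for i in range(n)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
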