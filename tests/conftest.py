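import numpy as np
import pytest

from bmrf.network_io import NEG, POS, UNKNOWN, ProteinNetwork


@pytest.fixture
def star_network():
    """Center 'c' with five leaves l0..l4."""
    leaves = [f"l{i}" for i in range(5)]
    return ProteinNetwork(["c"] + leaves, [("c", leaf) for leaf in leaves])


@pytest.fixture
def triangle_network():
    return ProteinNetwork(["a", "b", "c"], [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def six_node_network():
    """The small partially labeled graph used for enumeration oracles."""
    nodes = list("abcdef")
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("b", "e")]
    return ProteinNetwork(nodes, edges)


@pytest.fixture(scope="session")
def six_node_labels():
    # a, c observed positive; d, f observed negative; b, e unknown
    return np.array([POS, UNKNOWN, POS, NEG, UNKNOWN, NEG], dtype=np.int8)


def random_network(rng: np.random.Generator, n: int, p: float) -> ProteinNetwork:
    """Small Erdos-Renyi helper for oracle tests (independent of bmrf.synthetic)."""
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return ProteinNetwork(nodes, edges)
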