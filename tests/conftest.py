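import networkx as nx
import numpy as np
import pytest

from netpharm.synthetic import SimConfig, gen_bundle


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic bundle shared across tests (seed 1)."""
    return gen_bundle(SimConfig(seed=1))


@pytest.fixture()
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture()
def star5():
    """Star K1,4: center HUB, leaves L1..L4."""
    g = nx.Graph()
    g.add_edges_from([("HUB", f"L{i}") for i in range(1, 5)])
    return g


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph with string node labels."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"N{i}" for i in g})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
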