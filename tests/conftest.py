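import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def k3():
    return nx.complete_graph(["a", "b", "c"])


@pytest.fixture
def star4():
    """Star with center 'h' and 4 leaves."""
    g = nx.Graph()
    g.add_edges_from([("h", f"l{i}") for i in range(1, 5)])
    return g


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


@pytest.fixture
def rg12():
    return random_graph(12, 0.3, seed=5)
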