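import numpy as np
import pytest

from pepfam.scoring import ScoringScheme


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_graph(rng, n_nodes: int, edge_prob: float = 0.3):
    """Random weighted graph with no isolated nodes (weights in (0, 1])."""
    import networkx as nx

    g = nx.Graph()
    names = [f"n{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                g.add_edge(names[i], names[j], weight=float(rng.uniform(0.05, 1.0)))
    # connect isolated nodes so degree >= 1 everywhere
    for i, node in enumerate(names):
        if g.degree(node) == 0:
            other = names[(i + 1) % n_nodes]
            g.add_edge(node, other, weight=float(rng.uniform(0.05, 1.0)))
    return g
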