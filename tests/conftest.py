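import networkx as nx
import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def path_graph():
    """s - v - t with unit weights; s and t are the seeds."""
    g = nx.Graph()
    g.add_edge("s", "v", weight=1.0)
    g.add_edge("v", "t", weight=1.0)
    return g


@pytest.fixture
def toy_expression():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(20)]
    return pd.DataFrame(
        rng.standard_normal((6, 20)), index=pd.Index(genes, name="gene"), columns=samples
    )


def random_weighted_graph(rng, n, edge_prob=0.5, min_edges=2):
    """A random connected-ish simple graph with weights in (0.1, 1]."""
    while True:
        g = nx.Graph()
        nodes = [f"n{i}" for i in range(n)]
        g.add_nodes_from(nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.uniform() < edge_prob:
                    g.add_edge(nodes[i], nodes[j], weight=float(rng.uniform(0.1, 1.0)))
        if g.number_of_edges() >= min_edges:
            return g
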