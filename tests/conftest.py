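import random

import networkx as nx
import pytest

from pewcc import synthetic


@pytest.fixture
def fig2():
    """5-protein / 6-interaction reliability worked example."""
    return synthetic.fixture_fig2()


@pytest.fixture
def fig3():
    """6-protein / 12-interaction peeling worked example."""
    return synthetic.fixture_fig3()


def random_graph(n_nodes: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph with string node labels (zero-padded for lex order)."""
    rng = random.Random(seed)
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g
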