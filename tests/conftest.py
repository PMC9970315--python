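import networkx as nx
import numpy as np
import pytest

from regpath.network import RegNetwork


def digraph_network(edges, nodes=None):
    """RegNetwork over gene nodes with one directed arc per (u, v) pair.

    Used to exercise the traversal engine on arbitrary digraphs; each arc
    is typed ``ppi`` (the traversal is type-agnostic unless filtered).
    """
    g = nx.MultiDiGraph()
    for n in nodes or sorted({x for e in edges for x in e}):
        g.add_node(n, node_type="gene", role="none")
    for u, v in edges:
        g.add_edge(u, v, key="ppi", edge_type="ppi", provenance="test")
    return RegNetwork(graph=g)


def random_digraph_edges(rng, n_nodes, edge_prob):
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (u, v)
        for u in nodes
        for v in nodes
        if u != v and rng.random() < edge_prob
    ]
    return nodes, edges


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
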