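import networkx as nx
import numpy as np
import pytest

from pignon.annotations import AnnotationCatalog


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def triangle():
    """Unit-weight triangle A-B-C."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "A")], weight=1.0)
    return g


@pytest.fixture
def weighted_path():
    """A-B (0.5), B-C (0.25): the only A-C path sums to 0.75."""
    g = nx.Graph()
    g.add_edge("A", "B", weight=0.5)
    g.add_edge("B", "C", weight=0.25)
    return g


@pytest.fixture
def five_node_graph():
    """Triangle A-B-C plus path C-D-E, unit weights."""
    g = nx.Graph()
    g.add_edges_from(
        [("A", "B"), ("B", "C"), ("C", "A"), ("C", "D"), ("D", "E")], weight=1.0
    )
    return g


@pytest.fixture
def small_catalog():
    return AnnotationCatalog(
        terms={
            "GO:1": {"A", "B", "C"},
            "GO:2": {"C", "D", "E"},
            "GO:3": {"A", "E"},
        },
        names={"GO:1": "term one", "GO:2": "term two", "GO:3": "term three"},
    )


def random_connected_weighted_graph(n, rng, p_extra=0.15):
    """Random spanning tree plus extra edges; weights in (0.05, 1]."""
    g = nx.Graph()
    nodes = [f"N{i}" for i in range(n)]
    g.add_node(nodes[0])
    for i in range(1, n):
        j = int(rng.integers(0, i))
        g.add_edge(nodes[i], nodes[j], weight=float(0.05 + 0.95 * rng.random()))
    for i in range(n):
        for j in range(i + 1, n):
            if not g.has_edge(nodes[i], nodes[j]) and rng.random() < p_extra:
                g.add_edge(nodes[i], nodes[j],
                           weight=float(0.05 + 0.95 * rng.random()))
    return g


def bellman_ford_oracle(g):
    """Independent per-source Bellman-Ford all-pairs distances.

    Deliberately naive (edge-relaxation to fixpoint); serves as the oracle
    the Dijkstra-based implementation is checked against.
    """
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v], data["weight"]) for u, v, data in g.edges(data=True)]
    n = len(nodes)
    d = np.full((n, n), np.inf)
    for s in range(n):
        dist = d[s]
        dist[s] = 0.0
        for _ in range(n - 1):
            changed = False
            for u, v, w in edges:
                if dist[u] + w < dist[v]:
                    dist[v] = dist[u] + w
                    changed = True
                if dist[v] + w < dist[u]:
                    dist[u] = dist[v] + w
                    changed = True
            if not changed:
                break
    return index, d
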