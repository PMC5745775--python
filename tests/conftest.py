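import itertools

import networkx as nx
import numpy as np
import pytest

from homst.mining import LabeledGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_subject():
    """Deterministic 3-ROI subject for windowed-correlation checks."""
    from homst.synthetic import ROITimeSeriesSet

    series = np.array(
        [[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1], [1, 3, 2, 4, 3, 5]], dtype=float
    )
    return ROITimeSeriesSet("toy", 0, series)


def make_labeled_graph(edges, node_labels=None):
    """LabeledGraph from an edge list; labels default to node identity."""
    g = LabeledGraph()
    nodes = sorted({v for e in edges for v in e[:2]})
    for v in nodes:
        g.add_node(v, v if node_labels is None else node_labels[v])
    for e in edges:
        g.add_edge(e[0], e[1], e[2] if len(e) > 2 else 0)
    return g


def random_labeled_graph(rng, n_nodes, n_edges, n_labels=None):
    """Random connected-or-not labeled graph for mining oracles."""
    g = LabeledGraph()
    for v in range(n_nodes):
        g.add_node(v, v if n_labels is None else int(rng.integers(n_labels)))
    possible = list(itertools.combinations(range(n_nodes), 2))
    rng.shuffle(possible)
    for u, v in possible[:n_edges]:
        g.add_edge(u, v, 0)
    return g


def connected_edge_subsets(g):
    """Brute force: every connected subgraph over nonempty edge subsets."""
    edges = list(g.edges())
    out = []
    for r in range(1, len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            sub = LabeledGraph()
            for u, v, el in combo:
                for w in (u, v):
                    if w not in sub.node_labels:
                        sub.add_node(w, g.node_labels[w])
                sub.add_edge(u, v, el)
            if sub.is_connected():
                out.append(sub)
    return out


def all_spanning_trees_weight(w):
    """Maximum spanning-tree weight by Prüfer-sequence enumeration (n <= 7)."""
    n = w.shape[0]
    if n == 2:
        return w[0, 1]
    best = -np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        tree = nx.from_prufer_sequence(list(seq))
        total = sum(w[u, v] for u, v in tree.edges)
        best = max(best, total)
    return best
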