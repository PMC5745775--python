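"""Strongest-weight spanning tree and its local node metrics.

The dense P x P high-order network is reduced to its backbone: the
spanning tree retaining the strongest connection weights, built by
Kruskal's algorithm with edges considered in *descending* weight order
(formally a maximum-weight spanning tree).  Three node metrics are then
read off the tree: degree, eccentricity (longest hop distance to any
other node) and betweenness centrality normalized over ordered node
pairs so that a star center scores exactly 1.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

__all__ = ["kruskal_strongest_tree", "tree_metrics", "METRIC_NAMES"]

METRIC_NAMES = ("degree", "eccentricity", "betweenness")


def kruskal_strongest_tree(weights: np.ndarray | nx.Graph, absolute: bool = False) -> nx.Graph:
    """Spanning tree of maximal total weight via descending-order Kruskal.

    Parameters
    ----------
    weights : array or graph
        Either a symmetric n x n weight matrix (the diagonal is ignored)
        or a weighted undirected ``networkx`` graph.
    absolute : bool
        Rank edges by absolute weight instead of signed weight.  Off by default:
        the strongest *positive* couplings form the backbone.

    Ties are broken deterministically by (min node, max node) so identical
    inputs give identical trees across runs and platforms.
    """
    if isinstance(weights, nx.Graph):
        g = weights
        nodes = sorted(g.nodes)
        iu, ju, wt = [], [], []
        for u, v, d in g.edges(data=True):
            a, b = (u, v) if u <= v else (v, u)
            iu.append(a)
            ju.append(b)
            wt.append(float(d["weight"]))
        iu, ju, wt = np.asarray(iu), np.asarray(ju), np.asarray(wt)
    else:
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, equal_nan=False):
            raise ValueError("weight matrix must be symmetric")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        n = w.shape[0]
        nodes = list(range(n))
        iu, ju = np.triu_indices(n, k=1)
        wt = w[iu, ju]
    if not np.all(np.isfinite(wt)):
        raise ValueError("weights must be finite")

    rank = np.abs(wt) if absolute else wt
    # descending weight, ties by (min node, max node); lexsort keys are
    # least-significant first
    order = np.lexsort((ju, iu, -rank))

    tree = nx.Graph()
    tree.add_nodes_from(nodes)
    uf = nx.utils.UnionFind(nodes)
    n_edges = 0
    for pos in order:
        u, v, edge_w = int(iu[pos]), int(ju[pos]), float(wt[pos])
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree.add_edge(u, v, weight=edge_w)
            n_edges += 1
            if n_edges == len(nodes) - 1:
                break
    if n_edges != len(nodes) - 1:
        raise ValueError("input graph is disconnected; no spanning tree exists")
    return tree


def tree_metrics(tree: nx.Graph) -> pd.DataFrame:
    """Per-node degree, eccentricity and betweenness of a tree.

    Eccentricity and betweenness use hop (unweighted) distances, the
    convention of the spanning-tree connectome literature.  Betweenness is
    ``BC_i = sum_{h!=i!=j} [i on the h-j path] / ((n-1)(n-2))`` over
    ordered pairs — on a tree every node pair has exactly one path, so the
    star center attains 1.  ``networkx``'s normalized betweenness computes
    exactly this quantity.

    Returns a DataFrame indexed by node with columns ``degree``,
    ``eccentricity``, ``betweenness``.
    """
    n = tree.number_of_nodes()
    if n < 3:
        raise ValueError("betweenness normalizer (n-1)(n-2) needs n >= 3")
    if tree.number_of_edges() != n - 1 or not nx.is_connected(tree):
        raise ValueError("input is not a tree (need connected, n-1 edges)")
    nodes = sorted(tree.nodes)
    ecc = nx.eccentricity(tree)
    bc = nx.betweenness_centrality(tree, normalized=True)
    table = pd.DataFrame(
        {
            "degree": [tree.degree(v) for v in nodes],
            "eccentricity": [ecc[v] for v in nodes],
            "betweenness": [bc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return table
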