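"""Frequent connected subgraph mining (gSpan) and discriminative scoring.

Subjects' spanning trees form two graph databases (one per class).  gSpan
enumerates every connected subgraph pattern whose frequency — the
fraction of database graphs containing it — clears a threshold, using
minimum depth-first-search (DFS) codes as canonical labels, rightmost-path
extension to generate candidates, and the anti-monotonicity of frequency
to prune.  Patterns are then scored by the difference of their two group
frequencies, S = fq(pos) - fq(neg) in [-1, 1], and a balanced top-k per
direction is kept.

Node labels default to pair-node *identity* (subjects share one node
universe), which collapses pattern containment to label-respecting
edge-set inclusion; a degree-label mode is available for generality, in
which containment falls back to VF2 subgraph monomorphism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, NamedTuple

import networkx as nx
import numpy as np

__all__ = [
    "LabeledGraph",
    "SubgraphPattern",
    "tree_to_labeled_graph",
    "frequency",
    "contains",
    "min_dfs_code",
    "gspan_mine",
    "discriminative_scores",
    "select_top_k",
    "subject_pattern_graph",
]


class LabeledGraph:
    """Undirected graph with hashable node labels and edge labels.

    Nodes are integer ids; ``label(v)`` is the mining alphabet symbol.
    Edge labels default to the constant 0 (spanning trees are mined
    unweighted).
    """

    def __init__(self):
        self.node_labels: dict[int, Hashable] = {}
        self.adj: dict[int, dict[int, Hashable]] = {}

    def add_node(self, v: int, label: Hashable) -> None:
        self.node_labels[v] = label
        self.adj.setdefault(v, {})

    def add_edge(self, u: int, v: int, elabel: Hashable = 0) -> None:
        if u == v:
            raise ValueError("self-loops not allowed")
        if u not in self.node_labels or v not in self.node_labels:
            raise KeyError("add both endpoints before the edge")
        self.adj[u][v] = elabel
        self.adj[v][u] = elabel

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.adj.values()) // 2

    def edges(self) -> Iterable[tuple[int, int, Hashable]]:
        for u, nbrs in self.adj.items():
            for v, el in nbrs.items():
                if u < v:
                    yield u, v, el

    def is_connected(self) -> bool:
        if not self.node_labels:
            return True
        seen = set()
        stack = [next(iter(self.node_labels))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self.adj[u])
        return len(seen) == len(self.node_labels)

    def has_distinct_labels(self) -> bool:
        labels = list(self.node_labels.values())
        return len(set(labels)) == len(labels)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for v, lb in self.node_labels.items():
            g.add_node(v, label=lb)
        for u, v, el in self.edges():
            g.add_edge(u, v, elabel=el)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, label_attr: str = "label") -> "LabeledGraph":
        out = cls()
        for v, data in g.nodes(data=True):
            out.add_node(v, data.get(label_attr, v))
        for u, v, data in g.edges(data=True):
            out.add_edge(u, v, data.get("elabel", 0))
        return out


def tree_to_labeled_graph(tree: nx.Graph, labels: str = "identity") -> LabeledGraph:
    """Convert a subject's spanning tree into a mining graph.

    ``labels="identity"`` labels each node by its own id (pair-node
    index), the mode under which mined patterns decode to anatomy;
    ``labels="degree"`` labels nodes by their degree, the classic
    unlabeled-graph convention.
    """
    g = LabeledGraph()
    if labels == "identity":
        for v in tree.nodes:
            g.add_node(v, v)
    elif labels == "degree":
        for v in tree.nodes:
            g.add_node(v, tree.degree(v))
    else:
        raise ValueError(f"unknown label mode {labels!r}")
    for u, v in tree.edges:
        g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# DFS codes
# ---------------------------------------------------------------------------

class DFSEdge(NamedTuple):
    """One 5-tuple of a DFS code: discovery indices plus labels."""

    frm: int
    to: int
    vlb_frm: Hashable
    elb: Hashable
    vlb_to: Hashable


DFSCode = tuple[DFSEdge, ...]


def _code_graph(code: DFSCode) -> LabeledGraph:
    """Rebuild the pattern graph a DFS code describes."""
    g = LabeledGraph()
    for e in code:
        for v, lb in ((e.frm, e.vlb_frm), (e.to, e.vlb_to)):
            if v not in g.node_labels:
                g.add_node(v, lb)
        g.add_edge(e.frm, e.to, e.elb)
    return g


def _rmpath(code: DFSCode) -> list[int]:
    """Indices of the rightmost path's forward edges, rightmost first."""
    path: list[int] = []
    old_frm = None
    for i in range(len(code) - 1, -1, -1):
        e = code[i]
        if e.frm < e.to and (old_frm is None or e.to == old_frm):
            path.append(i)
            old_frm = e.frm
    return path


class _PDFS(NamedTuple):
    """One embedding step: (graph id, (from vertex, to vertex), previous)."""

    gid: int
    frm: int
    to: int
    prev: "object"


class _History:
    """Vertices and directed edge steps along one embedding chain."""

    __slots__ = ("steps", "vertices", "edge_set")

    def __init__(self, p: _PDFS):
        chain = []
        while p is not None:
            chain.append(p)
            p = p.prev
        chain.reverse()
        self.steps = [(p.frm, p.to) for p in chain]
        self.vertices = set()
        self.edge_set = set()
        for u, v in self.steps:
            self.vertices.update((u, v))
            self.edge_set.add(frozenset((u, v)))


def min_dfs_code(g: LabeledGraph) -> DFSCode:
    """Minimum DFS code of a connected labeled graph (its canonical form).

    Built greedily: keep every embedding of the current minimal prefix
    and repeatedly append the lexicographically smallest legal extension
    (backward edges from the rightmost vertex before forward edges from
    the rightmost path; among forward edges, deeper origins first).
    """
    if g.n_edges == 0:
        raise ValueError("minimum DFS code undefined for an edgeless graph")
    if not g.is_connected():
        raise ValueError("pattern graph must be connected")

    # seed: minimal 1-edge code over all directed orientations
    best = None
    for u, v, el in g.edges():
        for a, b in ((u, v), (v, u)):
            key = (g.node_labels[a], el, g.node_labels[b])
            if best is None or key < best:
                best = key
    code: list[DFSEdge] = [DFSEdge(0, 1, best[0], best[1], best[2])]
    projections = [
        _PDFS(0, a, b, None)
        for u, v, el in g.edges()
        for a, b in ((u, v), (v, u))
        if (g.node_labels[a], el, g.node_labels[b]) == best
    ]

    while len(code) < g.n_edges:
        rmpath = _rmpath(tuple(code))
        maxtoc = code[rmpath[0]].to
        # candidate key: (0, to, elb) backward | (1, -frm, elb, vlb) forward
        candidates: dict[tuple, list[_PDFS]] = {}
        for p in projections:
            hist = _History(p)
            # map graph vertices to DFS indices along this embedding
            vmap: dict[int, int] = {}
            for step_idx, (u, v) in enumerate(hist.steps):
                e = code[step_idx]
                vmap.setdefault(u, e.frm)
                vmap.setdefault(v, e.to)
            inv = {d: gv for gv, d in vmap.items()}
            right = inv[maxtoc]
            # backward: rightmost vertex -> rmpath vertex, unused edge
            for i in rmpath[::-1]:
                tgt = inv[code[i].frm]
                if tgt in g.adj[right] and frozenset((right, tgt)) not in hist.edge_set:
                    key = (0, code[i].frm, g.adj[right][tgt])
                    candidates.setdefault(key, []).append(_PDFS(0, right, tgt, p))
            # forward: from each rightmost-path vertex to an unvisited vertex
            for dfs_idx in [maxtoc] + [code[i].frm for i in rmpath]:
                src = inv[dfs_idx]
                for nbr, el in g.adj[src].items():
                    if nbr in hist.vertices:
                        continue
                    key = (1, -dfs_idx, el, g.node_labels[nbr])
                    candidates.setdefault(key, []).append(_PDFS(0, src, nbr, p))
        if not candidates:  # disconnected remainder cannot happen on connected g
            raise RuntimeError("extension exhausted before covering all edges")
        key = min(candidates)
        if key[0] == 0:
            _, to, elb = key
            code.append(DFSEdge(maxtoc, to, _vlb(code, maxtoc), elb, _vlb(code, to)))
        else:
            _, neg_frm, elb, vlb_to = key
            frm = -neg_frm
            code.append(DFSEdge(frm, maxtoc + 1, _vlb(code, frm), elb, vlb_to))
        projections = candidates[key]
    return tuple(code)


def _vlb(code: list[DFSEdge], dfs_idx: int) -> Hashable:
    """Label of an already-discovered DFS vertex."""
    for e in code:
        if e.frm == dfs_idx:
            return e.vlb_frm
        if e.to == dfs_idx:
            return e.vlb_to
    raise KeyError(dfs_idx)


# ---------------------------------------------------------------------------
# containment and frequency
# ---------------------------------------------------------------------------

def contains(g: LabeledGraph, pattern: LabeledGraph) -> bool:
    """Does ``g`` contain ``pattern`` as a (label-respecting) subgraph?

    Fast path when both graphs carry pairwise-distinct node labels (the
    identity-label mode): the embedding is forced, so containment is
    edge-set inclusion.  Otherwise VF2 subgraph monomorphism.
    """
    if pattern.n_nodes == 0:
        return True
    if pattern.has_distinct_labels() and g.has_distinct_labels():
        by_label = {lb: v for v, lb in g.node_labels.items()}
        for u, v, el in pattern.edges():
            gu = by_label.get(pattern.node_labels[u])
            gv = by_label.get(pattern.node_labels[v])
            if gu is None or gv is None or g.adj[gu].get(gv) != el:
                return False
        return True
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g.to_networkx(),
        pattern.to_networkx(),
        node_match=lambda a, b: a["label"] == b["label"],
        edge_match=lambda a, b: a["elabel"] == b["elabel"],
    )
    return matcher.subgraph_is_monomorphic()


def frequency(pattern: LabeledGraph, graphs: list[LabeledGraph]) -> float:
    """Fraction of database graphs containing the pattern."""
    if not graphs:
        raise ValueError("empty graph database")
    if not pattern.is_connected():
        raise ValueError("pattern must be connected")
    return sum(contains(g, pattern) for g in graphs) / len(graphs)


# ---------------------------------------------------------------------------
# gSpan
# ---------------------------------------------------------------------------

@dataclass
class SubgraphPattern:
    """A mined connected pattern with its canonical code and frequencies."""

    code: DFSCode
    graph: LabeledGraph = field(repr=False)
    fq: float = 0.0           # frequency in the database it was mined from
    fq_pos: float | None = None
    fq_neg: float | None = None

    @property
    def n_edges(self) -> int:
        return len(self.code)

    @property
    def score(self) -> float | None:
        if self.fq_pos is None or self.fq_neg is None:
            return None
        return self.fq_pos - self.fq_neg


class _GSpan:
    def __init__(self, graphs: list[LabeledGraph], min_count: int, max_edges: int):
        self.graphs = graphs
        self.min_count = min_count
        self.max_edges = max_edges
        self.found: list[SubgraphPattern] = []

    def run(self) -> list[SubgraphPattern]:
        seeds: dict[tuple, list[_PDFS]] = {}
        for gid, g in enumerate(self.graphs):
            for u, v, el in g.edges():
                for a, b in ((u, v), (v, u)):
                    key = (g.node_labels[a], el, g.node_labels[b])
                    seeds.setdefault(key, []).append(_PDFS(gid, a, b, None))
        for key in sorted(seeds):
            projected = seeds[key]
            if self._support(projected) < self.min_count:
                continue
            code = (DFSEdge(0, 1, *key),)
            self._grow(code, projected)
        return self.found

    @staticmethod
    def _support(projected: list[_PDFS]) -> int:
        return len({p.gid for p in projected})

    def _grow(self, code: DFSCode, projected: list[_PDFS]) -> None:
        support = self._support(projected)
        if support < self.min_count:
            return
        if min_dfs_code(_code_graph(code)) != code:
            return  # non-minimal DFS code: this pattern was/will be found elsewhere
        self.found.append(
            SubgraphPattern(code, _code_graph(code), fq=support / len(self.graphs))
        )
        if len(code) >= self.max_edges:
            return

        rmpath = _rmpath(code)
        maxtoc = code[rmpath[0]].to
        backward: dict[tuple, list[_PDFS]] = {}
        forward: dict[tuple, list[_PDFS]] = {}
        for p in projected:
            g = self.graphs[p.gid]
            hist = _History(p)
            vmap: dict[int, int] = {}
            for step_idx, (u, v) in enumerate(hist.steps):
                e = code[step_idx]
                vmap.setdefault(u, e.frm)
                vmap.setdefault(v, e.to)
            inv = {d: gv for gv, d in vmap.items()}
            right = inv[maxtoc]
            for i in rmpath[::-1]:
                tgt = inv[code[i].frm]
                if tgt in g.adj[right] and frozenset((right, tgt)) not in hist.edge_set:
                    key = (0, code[i].frm, g.adj[right][tgt])
                    backward.setdefault(key, []).append(_PDFS(p.gid, right, tgt, p))
            for dfs_idx in [maxtoc] + [code[i].frm for i in rmpath]:
                src = inv[dfs_idx]
                for nbr, el in g.adj[src].items():
                    if nbr in hist.vertices:
                        continue
                    key = (1, -dfs_idx, el, g.node_labels[nbr])
                    forward.setdefault(key, []).append(_PDFS(p.gid, src, nbr, p))

        for key in sorted(backward):
            _, to, elb = key
            child = code + (DFSEdge(maxtoc, to, _vlb(list(code), maxtoc), elb, _vlb(list(code), to)),)
            self._grow(child, backward[key])
        for key in sorted(forward):
            _, neg_frm, elb, vlb_to = key
            frm = -neg_frm
            child = code + (DFSEdge(frm, maxtoc + 1, _vlb(list(code), frm), elb, vlb_to),)
            self._grow(child, forward[key])


def gspan_mine(graphs: list[LabeledGraph], min_fq: float,
               max_edges: int = 10) -> list[SubgraphPattern]:
    """All connected patterns with frequency >= ``min_fq``, each once.

    Patterns are reported under their minimum DFS code; candidate
    generation follows rightmost-path extension and frequent patterns are
    grown only from frequent parents (anti-monotone pruning).  Pattern
    growth stops at ``max_edges`` edges (a safety valve for dense
    databases).
    """
    if not 0.0 < min_fq <= 1.0:
        raise ValueError(f"min_fq must lie in (0, 1], got {min_fq}")
    if not graphs:
        raise ValueError("empty graph database")
    # smallest count whose fraction clears min_fq, robust to float fuzz
    min_count = max(1, int(np.ceil(min_fq * len(graphs) - 1e-9)))
    return _GSpan(graphs, min_count, max_edges).run()


def discriminative_scores(
    patterns_pos: list[SubgraphPattern],
    patterns_neg: list[SubgraphPattern],
    graphs_pos: list[LabeledGraph],
    graphs_neg: list[LabeledGraph],
) -> list[SubgraphPattern]:
    """Score the pooled candidate patterns by frequency difference.

    The candidate pool is the union (by canonical code) of the two mined
    sets; each pattern's positive and negative frequencies are recomputed
    on the full graph lists and S = fq_pos - fq_neg attached.
    """
    if not graphs_pos or not graphs_neg:
        raise ValueError("both graph databases must be nonempty")
    pool: dict[DFSCode, SubgraphPattern] = {}
    for p in list(patterns_pos) + list(patterns_neg):
        pool.setdefault(p.code, p)
    scored = []
    for code, p in pool.items():
        q = SubgraphPattern(code, p.graph, fq=p.fq)
        q.fq_pos = frequency(p.graph, graphs_pos)
        q.fq_neg = frequency(p.graph, graphs_neg)
        scored.append(q)
    scored.sort(key=lambda s: (-s.score, s.code))
    return scored


def select_top_k(scored: list[SubgraphPattern], k: int) -> list[SubgraphPattern]:
    """Balanced top-k selection: k most positive plus k most negative.

    Positive direction requires S > 0, negative S < 0; ties break toward
    the pattern with larger own-group frequency, then canonical code
    order.  A shortfall on either side is warned about and the available
    patterns returned (selection stays balanced only if both sides have
    k candidates).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pos = sorted(
        (p for p in scored if p.score > 0),
        key=lambda p: (-p.score, -(p.fq_pos or 0.0), p.code),
    )
    neg = sorted(
        (p for p in scored if p.score < 0),
        key=lambda p: (p.score, -(p.fq_neg or 0.0), p.code),
    )
    for side, got in (("positive", pos), ("negative", neg)):
        if len(got) < k:
            warnings.warn(
                f"only {len(got)} {side}-direction discriminative patterns "
                f"available (requested {k})",
                stacklevel=2,
            )
    return pos[:k] + neg[:k]


def subject_pattern_graph(tree_graph: LabeledGraph,
                          patterns: list[SubgraphPattern]) -> LabeledGraph:
    """Subject-specific graph: the union of contained patterns' edges.

    For each selected pattern the subject's tree actually contains, the
    matched edges are copied; the result is the sub-structure of the tree
    spanned by the subject's discriminative patterns (possibly empty).
    """
    out = LabeledGraph()
    fast = tree_graph.has_distinct_labels()
    by_label = {lb: v for v, lb in tree_graph.node_labels.items()} if fast else None
    for pat in patterns:
        if fast and pat.graph.has_distinct_labels():
            if not contains(tree_graph, pat.graph):
                continue
            for u, v, el in pat.graph.edges():
                gu = by_label[pat.graph.node_labels[u]]
                gv = by_label[pat.graph.node_labels[v]]
                for w in (gu, gv):
                    if w not in out.node_labels:
                        out.add_node(w, tree_graph.node_labels[w])
                out.add_edge(gu, gv, el)
        else:
            matcher = nx.algorithms.isomorphism.GraphMatcher(
                tree_graph.to_networkx(),
                pat.graph.to_networkx(),
                node_match=lambda a, b: a["label"] == b["label"],
                edge_match=lambda a, b: a["elabel"] == b["elabel"],
            )
            for mapping in matcher.subgraph_monomorphisms_iter():
                inv = {pv: gv for gv, pv in mapping.items()}
                for u, v, el in pat.graph.edges():
                    gu, gv = inv[u], inv[v]
                    for w in (gu, gv):
                        if w not in out.node_labels:
                            out.add_node(w, tree_graph.node_labels[w])
                    out.add_edge(gu, gv, el)
    return out
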