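"""Plain-text serialization of pipeline artifacts.

Matrices travel as CSV, graphs as edge-list TSV (and GraphML where a
graph tool is the consumer), patterns as canonical DFS-code text with an
edge-list block, reports as JSON — everything diff-able and readable
without the package.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import PairIndex
from .mining import DFSEdge, LabeledGraph, SubgraphPattern, min_dfs_code

__all__ = [
    "save_matrix", "load_matrix",
    "save_tree", "load_tree",
    "save_pair_index",
    "save_patterns", "load_patterns",
    "save_kernel",
    "save_report", "save_roc",
    "checksum",
]


def save_matrix(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter=",", fmt="%.17g")


def load_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def save_tree(path, tree: nx.Graph, graphml: bool = False) -> None:
    """Edge-list TSV (node_q, node_r, weight); optional GraphML sibling."""
    with open(path, "w") as fh:
        fh.write("node_q\tnode_r\tweight\n")
        for u, v, d in sorted(
            (min(u, v), max(u, v), d) for u, v, d in tree.edges(data=True)
        ):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.17g}\n")
    if graphml:
        nx.write_graphml(tree, Path(path).with_suffix(".graphml"))


def load_tree(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(int(row["node_q"]), int(row["node_r"]), weight=float(row["weight"]))
    return g


def save_pair_index(path, idx: PairIndex) -> None:
    with open(path, "w") as fh:
        fh.write("pair_node\troi_i\troi_j\n")
        for q, (i, j) in enumerate(idx.pairs()):
            fh.write(f"{q}\t{i}\t{j}\n")


def save_patterns(path, patterns: list[SubgraphPattern]) -> None:
    """One block per pattern: header, canonical code lines, edge lines."""
    with open(path, "w") as fh:
        for i, p in enumerate(patterns):
            fh.write(
                f"#pattern {i} n_edges={p.n_edges} "
                f"fq_pos={p.fq_pos} fq_neg={p.fq_neg} score={p.score}\n"
            )
            for e in p.code:
                fh.write(f"code\t{e.frm}\t{e.to}\t{e.vlb_frm}\t{e.elb}\t{e.vlb_to}\n")
            for u, v, el in sorted(p.graph.edges()):
                fh.write(f"edge\t{u}\t{v}\t{el}\n")


def load_patterns(path) -> list[SubgraphPattern]:
    patterns: list[SubgraphPattern] = []
    code: list[DFSEdge] = []
    meta: dict = {}

    def flush():
        if not code:
            return
        g = LabeledGraph()
        for e in code:
            for v, lb in ((e.frm, e.vlb_frm), (e.to, e.vlb_to)):
                if v not in g.node_labels:
                    g.add_node(v, lb)
            g.add_edge(e.frm, e.to, e.elb)
        p = SubgraphPattern(tuple(code), g)
        p.fq_pos = meta.get("fq_pos")
        p.fq_neg = meta.get("fq_neg")
        patterns.append(p)

    with open(path) as fh:
        for line in fh:
            if line.startswith("#pattern"):
                flush()
                code, meta = [], {}
                for tok in line.split()[2:]:
                    key, _, val = tok.partition("=")
                    meta[key] = None if val == "None" else float(val)
            elif line.startswith("code\t"):
                _, frm, to, vf, el, vt = line.rstrip("\n").split("\t")
                code.append(DFSEdge(int(frm), int(to), int(vf), int(el), int(vt)))
    flush()
    return patterns


def save_kernel(path, k: np.ndarray, subject_ids: list[str]) -> None:
    pd.DataFrame(k, index=subject_ids, columns=subject_ids).to_csv(path)


def save_report(path, report) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def save_roc(path, report) -> None:
    np.savetxt(path, report.roc, delimiter="\t", header="fpr\ttpr", comments="")


def checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def canonical_key(pattern: SubgraphPattern) -> tuple:
    """Stable identifier: the pattern's minimum DFS code."""
    return tuple(min_dfs_code(pattern.graph))
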