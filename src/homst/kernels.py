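"""Graph and vector kernels plus their normalized convex combination.

Two views of each subject enter the classifier: a vector of selected
local tree features (linear kernel after per-feature standardization)
and a labeled graph (Weisfeiler-Lehman subtree kernel).  Each Gram
matrix is normalized to unit diagonal, k*(x,y) = k(x,y)/sqrt(k(x,x)k(y,y)),
and the classifier consumes the convex combination
k = a * k_vector + (1 - a) * k_graph with a chosen on a grid.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from .mining import LabeledGraph

__all__ = [
    "wl_subtree_kernel",
    "vector_kernel",
    "normalize_kernel",
    "combine_kernels",
    "assert_psd",
]

logger = logging.getLogger(__name__)


def _wl_count_vectors(graphs: list[LabeledGraph], h: int,
                      degree_init: bool) -> list[Counter]:
    """Compressed-label counts per graph, accumulated over iterations 0..h.

    Refinement: new label = compression of (old label, sorted multiset of
    neighbor labels).  The compression dictionary is built in first-seen
    order over the given graph sequence, so values are reproducible run to
    run.  Refinement stops early once no graph's label partition changes.
    ``degree_init`` replaces initial labels by node degree — the classic
    rule for unlabeled graphs.
    """
    labels = []
    for g in graphs:
        if degree_init:
            labels.append({v: len(g.adj[v]) for v in g.node_labels})
        else:
            labels.append(dict(g.node_labels))
    counts = [Counter(lb.values()) for lb in labels]
    for it in range(h):
        compress: dict[tuple, int] = {}
        new_labels = []
        for g, lb in zip(graphs, labels):
            nlb = {}
            for v in lb:
                signature = (lb[v], tuple(sorted(lb[u] for u in g.adj[v])))
                nlb[v] = compress.setdefault(signature, len(compress))
            new_labels.append(nlb)
        # early stop once refinement no longer splits any label class,
        # judged on the disjoint union of all graphs
        stable = _partition(
            {(g_i, v): l for g_i, nlb in enumerate(new_labels) for v, l in nlb.items()}
        ) == _partition(
            {(g_i, v): l for g_i, lb in enumerate(labels) for v, l in lb.items()}
        )
        labels = new_labels
        # iteration-tagged keys keep rounds' count blocks disjoint
        for c, lb in zip(counts, labels):
            c.update((("wl", it, l) for l in lb.values()))
        if stable:
            break
    return counts


def _partition(labeling: dict) -> frozenset:
    groups: dict = {}
    for v, l in labeling.items():
        groups.setdefault(l, set()).add(v)
    return frozenset(frozenset(s) for s in groups.values())


def wl_subtree_kernel(graphs: list[LabeledGraph], h: int = 3,
                      degree_init: bool = False) -> np.ndarray:
    """Raw Weisfeiler-Lehman subtree Gram matrix.

    ``k(x, y)`` is the inner product of the two graphs' label-count
    vectors summed over refinement iterations 0..h.  An empty graph has a
    zero count vector, hence zero kernel row (its diagonal is handled at
    normalization).
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    counts = _wl_count_vectors(graphs, h, degree_init)
    n = len(graphs)
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ci, cj = counts[i], counts[j]
            if len(cj) < len(ci):
                ci, cj = cj, ci
            k[i, j] = k[j, i] = sum(c * cj.get(lbl, 0) for lbl, c in ci.items())
    return k


def vector_kernel(features: np.ndarray, train_mask: np.ndarray | None = None,
                  kind: str = "linear") -> np.ndarray:
    """Raw kernel on per-feature standardized feature vectors.

    Standardization statistics (mean, sd) come from the rows flagged by
    ``train_mask`` (all rows if None), so test subjects never leak into
    the scaling.  ``kind="linear"`` (default) or ``"rbf"`` with the
    median-heuristic bandwidth.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError(
            "no selected features: fall back to the graph kernel alone"
        )
    ref = x if train_mask is None else x[np.asarray(train_mask, dtype=bool)]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd
    if kind == "linear":
        return z @ z.T
    if kind == "rbf":
        sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
        bandwidth = np.median(sq[np.triu_indices_from(sq, k=1)]) or 1.0
        return np.exp(-sq / bandwidth)
    raise ValueError(f"unknown kernel kind {kind!r}")


def normalize_kernel(k: np.ndarray) -> np.ndarray:
    """Unit-diagonal normalization k*(x,y) = k(x,y)/sqrt(k(x,x) k(y,y)).

    Subjects with k(x,x) = 0 (e.g. an empty pattern graph) get an
    identity row/column — similar only to themselves — with a warning.
    """
    k = np.asarray(k, dtype=float)
    d = np.diag(k).copy()
    zero = d <= 0
    if zero.any():
        logger.warning(
            "kernel has %d subject(s) with zero self-similarity; "
            "their rows are set to identity", int(zero.sum()),
        )
        d[zero] = 1.0
    scale = 1.0 / np.sqrt(d)
    out = k * scale[:, None] * scale[None, :]
    out[zero, :] = 0.0
    out[:, zero] = 0.0
    np.fill_diagonal(out, 1.0)
    return out


def combine_kernels(kernels: list[np.ndarray], weights) -> np.ndarray:
    """Entrywise convex combination of same-shape kernel matrices."""
    w = np.asarray(weights, dtype=float)
    if len(kernels) != w.size:
        raise ValueError("one weight per kernel required")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("weights must be nonnegative and sum to 1")
    shapes = {np.asarray(k).shape for k in kernels}
    if len(shapes) != 1:
        raise ValueError(f"kernel shape mismatch: {shapes}")
    out = np.zeros(shapes.pop())
    for a, k in zip(w, kernels):
        out += a * np.asarray(k, dtype=float)
    return out


def assert_psd(k: np.ndarray, tol: float = 1e-8) -> None:
    """Raise if a symmetric kernel matrix is not PSD within tolerance."""
    k = np.asarray(k, dtype=float)
    if not np.allclose(k, k.T, atol=1e-10):
        raise ValueError("kernel matrix is not symmetric")
    min_eig = float(np.linalg.eigvalsh(k).min())
    if min_eig < -tol:
        raise ValueError(f"kernel matrix not PSD: min eigenvalue {min_eig}")
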