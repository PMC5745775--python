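"""Selection of discriminating local tree features.

Each subject contributes one value per (pair-node, metric) feature; a
two-sample Kolmogorov-Smirnov test compares the two groups feature by
feature and Benjamini-Hochberg step-up correction controls the false
discovery rate across the feature family.  Pair-nodes abnormal in at
least two of the three tree metrics are reported separately, and Relief
weighting quantifies how informative feature blocks are.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import PairIndex
from .tree import METRIC_NAMES

__all__ = [
    "ks_two_sample",
    "bh_select",
    "select_features",
    "abnormal_nodes",
    "relief_weights",
    "feature_matrix",
]


def feature_matrix(metric_tables: list[pd.DataFrame], labels: np.ndarray) -> pd.DataFrame:
    """Assemble subjects x features matrix from per-subject metric tables.

    Feature columns are a MultiIndex (node, metric); rows follow subject
    order and carry the class label in ``df.attrs["labels"]``.
    """
    if len(metric_tables) != len(labels):
        raise ValueError("one metric table per label required")
    wide = [t[list(METRIC_NAMES)].stack() for t in metric_tables]
    fm = pd.DataFrame([w.values for w in wide], columns=wide[0].index)
    fm.columns.names = ["node", "metric"]
    fm.attrs["labels"] = np.asarray(labels, dtype=int)
    return fm


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D is the supremum distance between the two empirical CDFs.  The
    asymptotic p-value is appropriate for the group sizes this pipeline
    targets (tens of subjects); an exact variant is available directly
    through :func:`scipy.stats.ks_2samp` where needed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_select(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q.

    Rejects all hypotheses with p <= p_(k*), where
    k* = max{k : p_(k) <= k q / m}.  Implemented via scipy's BH-adjusted
    p-values; decisions are monotone in p by construction.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = stats.false_discovery_control(p, method="bh")
    return adjusted <= q


def select_features(fm: pd.DataFrame, q: float = 0.05, labels=None) -> pd.DataFrame:
    """KS test per feature between the two classes, BH-corrected at q.

    Returns a per-feature table with columns ``D``, ``p`` and boolean
    ``selected`` (BH decision at level q), indexed like ``fm``'s columns.
    """
    y = np.asarray(fm.attrs["labels"] if labels is None else labels, dtype=int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    x = fm.to_numpy(dtype=float)
    a, b = x[y == classes[0]], x[y == classes[1]]
    d_stats = np.empty(x.shape[1])
    p_vals = np.empty(x.shape[1])
    for f in range(x.shape[1]):
        if np.ptp(a[:, f]) == 0 and np.ptp(b[:, f]) == 0 and a[0, f] == b[0, f]:
            d_stats[f], p_vals[f] = 0.0, 1.0  # constant feature: no signal
        else:
            d_stats[f], p_vals[f] = ks_two_sample(a[:, f], b[:, f])
    result = pd.DataFrame({"D": d_stats, "p": p_vals}, index=fm.columns)
    result["selected"] = bh_select(p_vals, q)
    return result


def abnormal_nodes(selection: pd.DataFrame, pair_index: PairIndex | None = None,
                   min_metrics: int = 2) -> pd.DataFrame:
    """Pair-nodes significant in at least ``min_metrics`` of the metrics.

    ``selection`` is the table from :func:`select_features` with a
    (node, metric) index.  When a :class:`PairIndex` is given, each
    reported pair-node is decoded back to its ROI pair.
    """
    if not isinstance(selection.index, pd.MultiIndex):
        raise ValueError("selection table must be indexed by (node, metric)")
    hits = selection["selected"].groupby(level="node").sum()
    flagged = hits[hits >= min_metrics]
    report = pd.DataFrame({"n_significant_metrics": flagged.astype(int)})
    for metric in selection.index.get_level_values("metric").unique():
        sub = selection.xs(metric, level="metric")
        report[f"p_{metric}"] = sub.loc[report.index, "p"]
    if pair_index is not None:
        decoded = [pair_index.pair(int(q)) for q in report.index]
        report["roi_i"] = [i for i, _ in decoded]
        report["roi_j"] = [j for _, j in decoded]
    return report


def relief_weights(fm: pd.DataFrame, n_iterations: int | None = None,
                   seed: int = 0, labels=None) -> tuple[pd.Series, float]:
    """Classic two-class Relief feature weights.

    For each sampled instance the weight of feature f moves by
    ``|x_f - nearmiss_f| - |x_f - nearhit_f|`` (features scaled to [0, 1]
    range first, the standard Relief normalization): features that
    separate the classes gain weight, irrelevant ones hover near zero.
    One nearest hit and one nearest miss (Euclidean distance); by default
    every subject is visited once, in seeded random order.

    Returns (per-feature weights, mean weight).
    """
    y = np.asarray(fm.attrs["labels"] if labels is None else labels, dtype=int)
    x = fm.to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("Relief needs exactly two classes")
    if counts.min() < 2:
        raise ValueError("Relief needs >= 2 subjects per class (nearest hit exists)")
    span = np.ptp(x, axis=0)
    scale = np.where(span > 0, span, 1.0)
    xs = (x - x.min(axis=0)) / scale
    rng = np.random.default_rng(seed)
    m = x.shape[0] if n_iterations is None else n_iterations
    order = rng.choice(x.shape[0], size=m, replace=(m > x.shape[0]))
    w = np.zeros(x.shape[1])
    for i in order:
        dist = np.linalg.norm(xs - xs[i], axis=1)
        dist[i] = np.inf
        same = y == y[i]
        hit = np.flatnonzero(same)[np.argmin(dist[same])]
        miss = np.flatnonzero(~same)[np.argmin(dist[~same])]
        w += np.abs(xs[i] - xs[miss]) - np.abs(xs[i] - xs[hit])
    weights = pd.Series(w / m, index=fm.columns, name="relief_weight")
    return weights, float(weights.mean())
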