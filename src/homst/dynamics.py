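"""Sliding-window correlation dynamics and the high-order network.

Stage one of the pipeline.  A subject's ROI x time matrix is cut into K
overlapping windows; each window yields a low-order functional
connectivity matrix (pairwise Pearson correlation of the windowed ROI
series).  Tracing one ROI pair across the K windows gives a correlation
time series; correlating those series against each other produces the
high-order network, a P x P matrix over "pair-nodes" (P = R(R-1)/2)
whose entries reflect co-fluctuation of connectivity — interactions among
up to four regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ROITimeSeriesSet

__all__ = [
    "WindowScheme",
    "make_windows",
    "pearson",
    "windowed_low_order",
    "PairIndex",
    "stack_correlation_series",
    "high_order",
    "subject_high_order",
]

#: Defaults used throughout: window length 90 samples, step 1.
DEFAULT_WINDOW = 90
DEFAULT_STEP = 1


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window layout: K = floor((M - N) / S) + 1 windows.

    Window k (0-based) covers columns ``[k*S, k*S + N)``.
    """

    n_timepoints: int
    window: int
    step: int

    @property
    def n_windows(self) -> int:
        return (self.n_timepoints - self.window) // self.step + 1

    def bounds(self) -> list[tuple[int, int]]:
        """Half-open [start, stop) column bounds of every window."""
        return [(k * self.step, k * self.step + self.window) for k in range(self.n_windows)]


def make_windows(n_timepoints: int, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP) -> WindowScheme:
    if not 1 <= window <= n_timepoints:
        raise ValueError(
            f"window length {window} must satisfy 1 <= N <= M={n_timepoints}"
        )
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    return WindowScheme(n_timepoints, window, step)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises on zero-variance input instead of returning NaN: a silent NaN
    here would poison every downstream high-order entry.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson needs two equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("pearson needs length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("pearson undefined for a zero-variance input")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def windowed_low_order(subject: ROITimeSeriesSet, scheme: WindowScheme) -> np.ndarray:
    """K x R x R stack of windowed correlation matrices.

    Entry ``[k, i, j]`` is the Pearson correlation of ROI rows i and j
    restricted to window k; each slice is symmetric with unit diagonal.
    A constant ROI subseries within any window is an error (named by
    window and ROI).
    """
    series = subject.series
    if series.shape[1] != scheme.n_timepoints:
        raise ValueError(
            f"subject {subject.subject_id} has {series.shape[1]} time points, "
            f"window scheme expects {scheme.n_timepoints}"
        )
    n_rois = series.shape[0]
    stack = np.empty((scheme.n_windows, n_rois, n_rois))
    for k, (start, stop) in enumerate(scheme.bounds()):
        segment = series[:, start:stop]
        sd = segment.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"subject {subject.subject_id}: constant subseries in window {k} "
                f"for ROI rows {dead.tolist()}"
            )
        c = np.corrcoef(segment)
        np.fill_diagonal(c, 1.0)
        stack[k] = np.clip(c, -1.0, 1.0)
    return stack


class PairIndex:
    """Bijection between unordered ROI pairs (i < j) and pair-node ids.

    Row-major order (0,1), (0,2), ..., (R-2, R-1); pair-node q of the
    high-order network therefore has a fixed, documented ROI-pair meaning.
    """

    def __init__(self, n_rois: int):
        if n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        self.n_rois = n_rois
        self._pairs = [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]
        self._index = {pair: q for q, pair in enumerate(self._pairs)}

    @property
    def n_pairs(self) -> int:
        return len(self._pairs)

    def pair(self, q: int) -> tuple[int, int]:
        return self._pairs[q]

    def index(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("no pair-node for a self-pair")
        return self._index[(i, j) if i < j else (j, i)]

    def pairs(self) -> list[tuple[int, int]]:
        return list(self._pairs)


def stack_correlation_series(stack: np.ndarray, idx: PairIndex | None = None) -> np.ndarray:
    """P x K matrix of per-pair correlation time series.

    Row q traces the windowed correlation of pair ``idx.pair(q)`` across
    windows; this is the upper triangle of the low-order stack unrolled in
    row-major pair order.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("expected a K x R x R correlation stack")
    n_rois = stack.shape[1]
    if idx is None:
        idx = PairIndex(n_rois)
    elif idx.n_rois != n_rois:
        raise ValueError(f"PairIndex is for {idx.n_rois} ROIs, stack has {n_rois}")
    rows, cols = np.triu_indices(n_rois, k=1)
    return stack[:, rows, cols].T.copy()


def high_order(series: np.ndarray) -> np.ndarray:
    """P x P high-order network: pairwise Pearson over correlation series.

    Requires K >= 3 windows (a correlation of shorter series carries no
    usable variation) and rejects constant rows, naming the offending
    pair-nodes.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("expected a P x K correlation-series matrix")
    n_windows = series.shape[1]
    if n_windows < 3:
        raise ValueError(
            f"high-order correlation needs K >= 3 windows, got K={n_windows}; "
            "shrink the window length or step"
        )
    sd = series.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"constant correlation series for pair-nodes {dead.tolist()}; "
            "high-order correlation undefined there"
        )
    h = np.corrcoef(series)
    np.fill_diagonal(h, 1.0)
    return np.clip(h, -1.0, 1.0)


def subject_high_order(subject: ROITimeSeriesSet, scheme: WindowScheme) -> np.ndarray:
    """Convenience composition: windows -> low-order stack -> high-order."""
    stack = windowed_low_order(subject, scheme)
    return high_order(stack_correlation_series(stack))
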