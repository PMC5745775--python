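"""Synthetic two-group cohorts of ROI time series.

Real resting-state cohorts for this kind of analysis are rarely shareable,
so every downstream stage is exercised on generated data: ROI x time
matrices whose *windowed-correlation dynamics* differ between two groups.
Group 1 subjects receive a slowly oscillating coupling weight on a chosen
set of ROI pairs; group 0 subjects receive the same mean coupling held
constant.  The class signal therefore lives in the correlation *time
series* (what the high-order network measures), not merely in the static
correlation level.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CohortConfig",
    "ROITimeSeriesSet",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated two-group cohort.

    Parameters
    ----------
    n_per_group : int
        Subjects per class (total cohort size is ``2 * n_per_group``).
    n_rois : int
        Number of regions of interest R (rows of each matrix). R >= 3.
    n_timepoints : int
        Time points M per series (columns). M >= 2.
    effect_pairs : tuple of (int, int), optional
        ROI index pairs (0-based, i != j, both < R) whose coupling is
        group-modulated; defaults to up to three disjoint pairs
        (0,1), (2,3), (4,5) clipped to the available ROIs.
    effect_size : float
        Amplitude of the oscillating coupling weight, in [0, 1].  0 makes
        the two groups draws from one process.
    noise_sd : float
        Standard deviation of additive Gaussian observation noise.
    seed : int
        RNG seed; identical configs give bit-identical cohorts.
    """

    n_per_group: int = 20
    n_rois: int = 10
    n_timepoints: int = 120
    effect_pairs: tuple | None = None
    effect_size: float = 0.8
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.effect_pairs is None:
            pairs = tuple((2 * i, 2 * i + 1) for i in range(min(3, self.n_rois // 2)))
            object.__setattr__(self, "effect_pairs", pairs)
        if self.n_per_group < 1:
            raise ValueError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if self.n_rois < 3:
            raise ValueError(f"n_rois must be >= 3, got {self.n_rois}")
        if self.n_timepoints < 2:
            raise ValueError(f"n_timepoints must be >= 2, got {self.n_timepoints}")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError(f"effect_size must lie in [0, 1], got {self.effect_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for pair in self.effect_pairs:
            i, j = pair
            if i == j:
                raise ValueError(f"effect pair {pair} repeats an ROI index")
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(
                    f"effect pair {pair} out of range for {self.n_rois} ROIs"
                )


@dataclass
class ROITimeSeriesSet:
    """One subject's ROI x time matrix with a binary class label."""

    subject_id: str
    label: int
    series: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError(f"subject {self.subject_id}: series must be 2-D")
        if self.label not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: label must be 0 or 1")
        if not np.all(np.isfinite(self.series)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in series")
        variances = self.series.var(axis=1)
        dead = np.flatnonzero(variances == 0)
        if dead.size:
            raise ValueError(
                f"subject {self.subject_id}: constant (zero-variance) "
                f"ROI rows {dead.tolist()}"
            )

    @property
    def n_rois(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


def _simulate_subject(rng: np.random.Generator, cfg: CohortConfig, dynamic: bool) -> np.ndarray:
    """One subject: latent sources plus pairwise coupling plus noise.

    Every ROI starts as an independent standard-normal source.  For each
    effect pair (i, j) the target ROI j is mixed with source i using a
    weight w(t); group 1 (``dynamic=True``) uses a slow sinusoid of
    amplitude ``effect_size`` (one cycle over the scan, so the drift is
    slow relative to any window; one random phase per subject shared by
    all effect pairs, so their correlation series co-fluctuate), group 0
    uses the sinusoid's mean held constant: the
    *average* coupling matches across groups and only its dynamics — the
    quantity the high-order network measures — differ.
    """
    R, M = cfg.n_rois, cfg.n_timepoints
    sources = rng.standard_normal((R, M))
    x = sources.copy()
    t = np.arange(M)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    for i, j in cfg.effect_pairs:
        if dynamic:
            w = cfg.effect_size * 0.5 * (1.0 + np.sin(2.0 * np.pi * t / M + phase))
        else:
            w = np.full(M, cfg.effect_size * 0.5)
        # unit-variance mixture of two independent unit-variance sources
        x[j] = np.sqrt(np.clip(1.0 - w**2, 0.0, None)) * sources[j] + w * sources[i]
    x += cfg.noise_sd * rng.standard_normal((R, M))
    return x


def generate_cohort(config: CohortConfig) -> list[ROITimeSeriesSet]:
    """Simulate ``2 * n_per_group`` labeled subjects.

    Group 0 subjects come first (``s000`` ...), then group 1.  The RNG is
    seeded once from ``config.seed``; repeated calls with the same config
    return bit-identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    cohort: list[ROITimeSeriesSet] = []
    for label in (0, 1):
        for k in range(config.n_per_group):
            idx = label * config.n_per_group + k
            series = _simulate_subject(rng, config, dynamic=bool(label))
            cohort.append(ROITimeSeriesSet(f"s{idx:03d}", label, series))
    return cohort


def write_cohort(cohort: list[ROITimeSeriesSet], directory: str | Path) -> None:
    """Write one CSV matrix per subject plus ``labels.csv``.

    Matrices are plain comma-delimited text, no header, one ROI per row,
    written with repr-precision floats so a read-back round-trips.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        for subject in cohort:
            writer.writerow([subject.subject_id, subject.label])
            np.savetxt(
                directory / f"{subject.subject_id}.csv",
                subject.series,
                delimiter=",",
                fmt="%.17g",
            )


def read_cohort(directory: str | Path) -> list[ROITimeSeriesSet]:
    """Read a cohort written by :func:`write_cohort` (or hand-prepared).

    Expects ``labels.csv`` with rows ``subject_id,label`` and one
    ``<subject_id>.csv`` matrix per row.  All subjects must share the
    matrix shape; constant ROI rows are rejected with the subject named.
    """
    directory = Path(directory)
    label_path = directory / "labels.csv"
    if not label_path.exists():
        raise FileNotFoundError(f"no label table at {label_path}")
    cohort: list[ROITimeSeriesSet] = []
    with open(label_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            subject_id, label_text = row[0].strip(), row[1].strip()
            if label_text not in ("0", "1"):
                raise ValueError(
                    f"subject {subject_id}: unknown label {label_text!r} (need 0 or 1)"
                )
            matrix_path = directory / f"{subject_id}.csv"
            if not matrix_path.exists():
                raise FileNotFoundError(f"subject {subject_id}: missing {matrix_path}")
            series = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
            cohort.append(ROITimeSeriesSet(subject_id, int(label_text), series))
    if not cohort:
        raise ValueError(f"empty label table {label_path}")
    shapes = {s.series.shape for s in cohort}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent matrix shapes across subjects: {sorted(shapes)}")
    return cohort
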