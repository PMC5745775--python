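"""Top-level modelling interface.

:class:`HighOrderTreeModel` wraps the whole pipeline the way a
statsmodels model wraps an estimator: construct it from a cohort of ROI
time-series matrices (or a directory, or a synthetic-cohort config),
call :meth:`~HighOrderTreeModel.fit`, and receive a
:class:`HighOrderTreeResults` carrying the cross-validated
classification report, the feature-selection and abnormal-node tables,
the discriminative subgraph patterns and a :meth:`summary` table.

Stages, per subject: sliding-window correlations -> correlation time
series over ROI pairs -> high-order (correlation-of-correlations)
network -> strongest-weight spanning tree -> local tree metrics.  Across
subjects: KS/BH feature selection, gSpan pattern mining with
discriminative scoring, WL-subtree and vector kernels, multikernel SVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import classify, dynamics, kernels, mining, selection, tree
from .synthetic import CohortConfig, ROITimeSeriesSet, generate_cohort, read_cohort

__all__ = ["PipelineConfig", "HighOrderTreeModel", "HighOrderTreeResults"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters (defaults are the intended operating point).

    window, step : sliding-window length N and stride S (samples).
    q : FDR level for KS/BH feature selection.
    fq_pos, fq_neg : mining frequency thresholds for the label-1 and
        label-0 groups.
    k_patterns : discriminative patterns kept per direction (2k total).
    max_pattern_edges : pattern growth cap (safety valve).
    wl_iterations : WL refinement rounds h.
    wl_degree_init : start WL from degree labels (unlabeled-graph rule)
        instead of pair-node identities.
    label_mode : node labels for mining, "identity" or "degree".
    tree_absolute : rank spanning-tree edges by |weight| instead of
        signed weight.
    """

    window: int = 90
    step: int = 1
    q: float = 0.05
    fq_pos: float = 0.286
    fq_neg: float = 0.211
    k_patterns: int = 16
    max_pattern_edges: int = 10
    wl_iterations: int = 3
    wl_degree_init: bool = False
    label_mode: str = "identity"
    tree_absolute: bool = False


class HighOrderTreeModel:
    """High-order spanning-tree connectivity classifier for a two-group cohort."""

    def __init__(self, cohort: list[ROITimeSeriesSet],
                 config: PipelineConfig | None = None, **overrides):
        if overrides:
            config = PipelineConfig(**{**asdict(config or PipelineConfig()), **overrides})
        self.config = config or PipelineConfig()
        if len(cohort) < 4:
            raise ValueError("need at least 4 subjects")
        self.cohort = cohort
        self.labels = np.array([s.label for s in cohort], dtype=int)
        if np.unique(self.labels).size != 2:
            raise ValueError("cohort must contain both classes")
        n_rois = cohort[0].n_rois
        self.pair_index = dynamics.PairIndex(n_rois)
        self.scheme = dynamics.make_windows(
            cohort[0].n_timepoints, self.config.window, self.config.step
        )
        self._prepared = False

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_directory(cls, path, **kwargs) -> "HighOrderTreeModel":
        """Build from a directory of per-subject CSV matrices + labels.csv."""
        return cls(read_cohort(path), **kwargs)

    @classmethod
    def from_synthetic(cls, cohort_config: CohortConfig, **kwargs) -> "HighOrderTreeModel":
        """Build from a freshly simulated two-group cohort."""
        return cls(generate_cohort(cohort_config), **kwargs)

    # -- per-subject stages ----------------------------------------------

    def _prepare(self) -> None:
        """High-order network, spanning tree and metrics for every subject."""
        if self._prepared:
            return
        self.high_order_: list[np.ndarray] = []
        self.trees_: list = []
        self.tree_graphs_: list[mining.LabeledGraph] = []
        metric_tables = []
        for subject in self.cohort:
            h = dynamics.subject_high_order(subject, self.scheme)
            t = tree.kruskal_strongest_tree(h, absolute=self.config.tree_absolute)
            self.high_order_.append(h)
            self.trees_.append(t)
            self.tree_graphs_.append(
                mining.tree_to_labeled_graph(t, labels=self.config.label_mode)
            )
            metric_tables.append(tree.tree_metrics(t))
        self.feature_matrix_ = selection.feature_matrix(metric_tables, self.labels)
        self._prepared = True

    # -- fold-wise kernel construction ------------------------------------

    def _mine_patterns(self, train_idx) -> list[mining.SubgraphPattern]:
        train_idx = np.asarray(train_idx)
        graphs_pos = [self.tree_graphs_[i] for i in train_idx if self.labels[i] == 1]
        graphs_neg = [self.tree_graphs_[i] for i in train_idx if self.labels[i] == 0]
        pats_pos = mining.gspan_mine(
            graphs_pos, self.config.fq_pos, max_edges=self.config.max_pattern_edges
        )
        pats_neg = mining.gspan_mine(
            graphs_neg, self.config.fq_neg, max_edges=self.config.max_pattern_edges
        )
        scored = mining.discriminative_scores(pats_pos, pats_neg, graphs_pos, graphs_neg)
        return mining.select_top_k(scored, self.config.k_patterns)

    def build_kernels(self, train_idx) -> list[np.ndarray]:
        """Normalized (vector, graph) kernels over all subjects.

        Everything data-dependent — KS/BH feature selection, pattern
        mining, standardization — uses only ``train_idx`` subjects.
        Returns a single-element list (graph kernel alone) when selection
        keeps no feature.
        """
        self._prepare()
        train_idx = np.asarray(train_idx)
        fm = self.feature_matrix_
        sel = selection.select_features(
            fm.iloc[train_idx], self.config.q, labels=self.labels[train_idx]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # pattern shortfall is routine per fold
            patterns = self._mine_patterns(train_idx)
        pattern_graphs = [
            mining.subject_pattern_graph(g, patterns) for g in self.tree_graphs_
        ]
        k_graph = kernels.normalize_kernel(
            kernels.wl_subtree_kernel(
                pattern_graphs,
                h=self.config.wl_iterations,
                degree_init=self.config.wl_degree_init,
            )
        )
        mask = sel["selected"].to_numpy()
        if not mask.any():
            return [k_graph]
        features = fm.loc[:, mask].to_numpy(dtype=float)
        train_mask = np.zeros(len(self.cohort), dtype=bool)
        train_mask[train_idx] = True
        k_vec = kernels.normalize_kernel(
            kernels.vector_kernel(features, train_mask=train_mask)
        )
        return [k_vec, k_graph]

    # -- fitting -----------------------------------------------------------

    def fit(self, protocol: classify.EvalProtocol | None = None) -> "HighOrderTreeResults":
        """Cross-validated fit; returns the results object."""
        self._prepare()
        protocol = protocol or classify.EvalProtocol()
        report = classify.cross_validate(self.build_kernels, self.labels, protocol)
        # whole-sample descriptive artifacts (for interpretation, not scoring)
        all_idx = np.arange(len(self.cohort))
        sel = selection.select_features(self.feature_matrix_, self.config.q)
        abnormal = selection.abnormal_nodes(sel, self.pair_index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            patterns = self._mine_patterns(all_idx)
        relief, relief_mean = selection.relief_weights(
            self.feature_matrix_, seed=protocol.seed
        )
        return HighOrderTreeResults(
            model=self, protocol=protocol, report=report, selection=sel,
            abnormal=abnormal, patterns=patterns,
            relief=relief, relief_mean=relief_mean,
        )


@dataclass
class HighOrderTreeResults:
    """Fit artifacts: CV report, selection tables, patterns, Relief weights."""

    model: HighOrderTreeModel
    protocol: classify.EvalProtocol
    report: classify.ClassificationReport
    selection: pd.DataFrame
    abnormal: pd.DataFrame
    patterns: list
    relief: pd.Series
    relief_mean: float

    def pattern_table(self) -> pd.DataFrame:
        """One row per selected discriminative pattern."""
        rows = []
        for i, p in enumerate(self.patterns):
            rows.append({
                "pattern": i,
                "n_edges": p.n_edges,
                "fq_pos": p.fq_pos,
                "fq_neg": p.fq_neg,
                "score": p.score,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        r = self.report
        cfg = self.model.config
        lines = [
            "High-order spanning-tree connectivity classification",
            "=" * 56,
            f"subjects: {len(self.model.cohort)}  "
            f"(class 1: {int(self.model.labels.sum())}, "
            f"class 0: {int((1 - self.model.labels).sum())})",
            f"ROIs: {self.model.pair_index.n_rois}  "
            f"pair-nodes: {self.model.pair_index.n_pairs}  "
            f"windows: {self.model.scheme.n_windows} "
            f"(N={cfg.window}, S={cfg.step})",
            f"protocol: {'whole-sample selection + LOO' if self.protocol.whole_sample else 'nested leave-one-out'}",
            "-" * 56,
            f"accuracy     {r.accuracy:8.4f}",
            f"sensitivity  {r.sensitivity:8.4f}",
            f"specificity  {r.specificity:8.4f}",
            f"AUC          {r.auc:8.4f}",
            f"confusion    TP={r.tp} TN={r.tn} FP={r.fp} FN={r.fn}",
            "-" * 56,
            f"selected features (BH q={cfg.q}): "
            f"{int(self.selection['selected'].sum())} / {len(self.selection)}",
            f"abnormal pair-nodes (>=2 metrics): {len(self.abnormal)}",
            f"discriminative patterns kept: {len(self.patterns)} "
            f"(k={cfg.k_patterns} per direction, fq>={cfg.fq_pos}/{cfg.fq_neg})",
            f"mean Relief weight: {self.relief_mean:.6f}",
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the pooled leave-one-out decision scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.report.roc[:, 0], self.report.roc[:, 1],
                label=f"AUC = {self.report.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax
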