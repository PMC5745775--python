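"""Multikernel SVM training, cross-validation and evaluation metrics.

The combined kernel k = a * k_vector + (1 - a) * k_graph (both already
unit-diagonal normalized) feeds a soft-margin SVM with a precomputed
Gram matrix.  The weighting parameter a is chosen on a grid
{0, 0.1, ..., 1.0} together with the SVM cost by inner cross-validated
accuracy on the training subjects; outer evaluation is leave-one-out,
with all data-dependent stages (feature selection, pattern mining,
kernel construction) re-run inside each training fold unless the
optimistic whole-sample mode is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .kernels import combine_kernels

__all__ = [
    "EvalProtocol",
    "ClassificationReport",
    "train_mksvm",
    "cross_validate",
    "report_metrics",
]

DEFAULT_A_GRID = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 1))
DEFAULT_COST_GRID = (0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class EvalProtocol:
    """Evaluation settings: grids, inner folds, seed, leakage mode.

    ``whole_sample=True`` reproduces the optimistic published-style
    protocol (selection and mining on the whole sample, leave-one-out on
    the classifier only); the default re-runs every data-dependent stage
    inside each training fold.
    """

    a_grid: tuple = DEFAULT_A_GRID
    cost_grid: tuple = DEFAULT_COST_GRID
    inner_folds: int = 5
    seed: int = 0
    whole_sample: bool = False

    def __post_init__(self):
        if not self.a_grid or not self.cost_grid:
            raise ValueError("grids must be nonempty")
        if any(not 0.0 <= a <= 1.0 for a in self.a_grid):
            raise ValueError("kernel weights must lie in [0, 1]")


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    tp: int
    tn: int
    fp: int
    fn: int
    roc: np.ndarray = field(repr=False)        # columns fpr, tpr
    truth: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    fold_choices: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
            "fold_choices": self.fold_choices,
        }


class MKSVM:
    """SVM over a fixed convex kernel combination, scoring by subject index."""

    def __init__(self, kernels: Sequence[np.ndarray], labels, a: float, cost: float,
                 train_idx=None):
        if not 0.0 <= a <= 1.0:
            raise ValueError("a must lie in [0, 1]")
        labels = np.asarray(labels, dtype=int)
        n = np.asarray(kernels[0]).shape[0]
        self.train_idx = np.arange(n) if train_idx is None else np.asarray(train_idx)
        if np.unique(labels[self.train_idx]).size < 2:
            raise ValueError("training fold contains a single class")
        self.combined = combine_kernels(list(kernels), (a, 1.0 - a))
        self.a, self.cost = a, cost
        # balanced class weighting: leave-one-out folds are never exactly
        # balanced, and an underfit SVM would otherwise drift to the
        # training majority (the opposite of the held-out class)
        self._svc = SVC(C=cost, kernel="precomputed", class_weight="balanced")
        gram = self.combined[np.ix_(self.train_idx, self.train_idx)]
        self._svc.fit(gram, labels[self.train_idx])

    def decision(self, idx) -> np.ndarray:
        idx = np.atleast_1d(np.asarray(idx))
        rows = self.combined[np.ix_(idx, self.train_idx)]
        return self._svc.decision_function(rows)

    def predict(self, idx) -> np.ndarray:
        classes = self._svc.classes_
        return np.where(self.decision(idx) > 0, classes[1], classes[0])


def train_mksvm(kernels: Sequence[np.ndarray], labels, a: float, cost: float,
                train_idx=None) -> MKSVM:
    """Fit the multikernel SVM; ``a`` weights the first (vector) kernel.

    ``kernels`` is (k_vector, k_graph), both normalized, over all
    subjects; ``train_idx`` restricts fitting to a fold (default: all).
    """
    return MKSVM(kernels, labels, a, cost, train_idx)


def _grid_search(kernels, labels, train_idx, protocol: EvalProtocol):
    """Pick (a, cost) by inner stratified-CV accuracy on the training fold.

    Ties break toward smaller a, then smaller cost, so the search is
    deterministic.
    """
    y = np.asarray(labels, dtype=int)[train_idx]
    n_splits = min(protocol.inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        return protocol.a_grid[0], protocol.cost_grid[0]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=protocol.seed)
    best = None
    for a in protocol.a_grid:
        for cost in protocol.cost_grid:
            correct = 0
            for inner_train, inner_test in skf.split(np.zeros(len(y)), y):
                tr = train_idx[inner_train]
                te = train_idx[inner_test]
                if np.unique(np.asarray(labels)[tr]).size < 2:
                    continue
                model = MKSVM(kernels, labels, a, cost, train_idx=tr)
                correct += int(np.sum(model.predict(te) == np.asarray(labels)[te]))
            key = (-correct, a, cost)
            if best is None or key < best:
                best = key
    return best[1], best[2]


def cross_validate(kernel_builder: Callable, labels,
                   protocol: EvalProtocol | None = None) -> ClassificationReport:
    """Leave-one-out evaluation with per-fold kernel construction.

    ``kernel_builder(train_idx)`` must return the (vector, graph) kernel
    pair over *all* subjects, built using only the given training
    subjects' information (selection, mining, scaling); it may return a
    single-element list, in which case the weight grid collapses.  In
    ``whole_sample`` the builder is called once with every subject.
    """
    protocol = protocol or EvalProtocol()
    y = np.asarray(labels, dtype=int)
    n = y.size
    if n < 6 or np.unique(y).size != 2:
        raise ValueError("need >= 6 subjects and both classes for LOO evaluation")
    shared = kernel_builder(np.arange(n)) if protocol.whole_sample else None
    scores = np.empty(n)
    choices = []
    for test in range(n):
        train_idx = np.delete(np.arange(n), test)
        kernels = shared if shared is not None else kernel_builder(train_idx)
        if len(kernels) == 1:
            kernels = [kernels[0], kernels[0]]
        a, cost = _grid_search(kernels, y, train_idx, protocol)
        model = MKSVM(kernels, y, a, cost, train_idx=train_idx)
        raw = float(model.decision([test])[0])
        # orient the score toward class 1 regardless of class order
        scores[test] = raw if model._svc.classes_[1] == 1 else -raw
        choices.append({"test_subject": test, "a": float(a), "cost": float(cost)})
    report = report_metrics(y, scores, positive_class=1)
    report.fold_choices = choices
    return report


def report_metrics(truth, scores, positive_class: int = 1) -> ClassificationReport:
    """Confusion metrics at decision threshold 0 plus trapezoidal AUC.

    ``scores`` are signed decision values oriented toward the positive
    class; constant scores give AUC 0.5 by the tie-handling convention of
    the trapezoidal rule.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = truth == positive_class
    if pos.all() or not pos.any():
        raise ValueError("AUC undefined with a single class in truth")
    pred_pos = scores > 0
    tp = int(np.sum(pred_pos & pos))
    tn = int(np.sum(~pred_pos & ~pos))
    fp = int(np.sum(pred_pos & ~pos))
    fn = int(np.sum(~pred_pos & pos))
    fpr, tpr, _ = roc_curve(pos.astype(int), scores, drop_intermediate=False)
    return ClassificationReport(
        accuracy=(tp + tn) / truth.size,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=float(_trapezoid_auc(fpr, tpr)),
        tp=tp, tn=tn, fp=fp, fn=fn,
        roc=np.column_stack([fpr, tpr]),
        truth=truth,
        scores=scores,
    )
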