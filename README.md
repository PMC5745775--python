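# homst — high-order spanning-tree functional connectivity

`homst` classifies subjects from region-of-interest (ROI) fMRI time series
by modelling the *dynamics* of functional connectivity rather than its
static level. It is aimed at researchers building connectome-based
classifiers (e.g. patient-vs-control studies) who start from parcellated
ROI × time matrices.

## The model

For subject *l* with ROI series *x_i(l)*, a sliding window of length *N*
and step *S* cuts the scan of length *M* into *K* = ⌊(M − N)/S⌋ + 1
segments. Each window *k* yields a low-order connectivity matrix
*C(l)(k)* of pairwise Pearson correlations. Tracing one ROI pair (*i*, *j*)
across windows gives its correlation time series
*y_ij(l)* = (C_ij(l)(1), …, C_ij(l)(K)), and the **high-order network** is
the P × P matrix (P = R(R−1)/2 pair-nodes)

&nbsp;&nbsp;&nbsp;&nbsp;H_ij,pq(l) = corr(y_ij(l), y_pq(l)),

which captures co-fluctuation of connectivity — interactions among up to
four regions. The dense H is reduced to its backbone by descending-order
Kruskal: the spanning tree keeping the strongest weights (a maximum-weight
spanning tree, P − 1 edges). Two feature families are extracted:

* **Local tree metrics** per pair-node — degree, eccentricity (hops),
  betweenness centrality normalized over ordered pairs — screened by
  two-sample Kolmogorov–Smirnov tests with Benjamini–Hochberg correction
  (q = 0.05); pair-nodes significant in ≥ 2 of 3 metrics are reported as
  abnormal connectivities.
* **Discriminative subgraph patterns** — gSpan mines each group's trees
  for frequent connected subgraphs (canonical minimum DFS codes,
  rightmost-path extension, anti-monotone pruning); each pattern is scored
  S(g) = fq(g | G⁺) − fq(g | G⁻) ∈ [−1, 1] and the balanced top-k per
  direction is kept.

Subjects are compared through two unit-diagonal–normalized kernels — a
linear kernel on the selected metric features and a Weisfeiler–Lehman
subtree kernel on each subject's pattern-restricted tree — combined
convexly, k = a·k_vec + (1 − a)·k_graph, with a ∈ {0, 0.1, …, 1} and the
SVM cost chosen by inner cross-validated grid search inside a nested
leave-one-out protocol. Relief weighting quantifies feature-block
informativeness.

## Worked example

```python
from homst import CohortConfig, EvalProtocol, HighOrderTreeModel, PipelineConfig

cohort = CohortConfig(n_per_group=20, n_rois=10, n_timepoints=120,
                      effect_size=0.8, noise_sd=0.2, seed=1)
model = HighOrderTreeModel.from_synthetic(cohort,
                                          config=PipelineConfig(window=30, step=1))
results = model.fit(EvalProtocol(seed=1))
print(results.summary())
```

prints

```
High-order spanning-tree connectivity classification
========================================================
subjects: 40  (class 1: 20, class 0: 20)
ROIs: 10  pair-nodes: 45  windows: 91 (N=30, S=1)
protocol: nested leave-one-out
--------------------------------------------------------
accuracy       0.8500
sensitivity    0.9000
specificity    0.8000
AUC            0.9000
confusion    TP=18 TN=16 FP=4 FN=2
--------------------------------------------------------
selected features (BH q=0.05): 0 / 135
abnormal pair-nodes (>=2 metrics): 0
discriminative patterns kept: 16 (k=16 per direction, fq>=0.286/0.211)
mean Relief weight: 0.004492
```

The synthetic group difference lives purely in coupling *dynamics* (three
ROI pairs whose mixing weight oscillates in one group and is held at the
same mean in the other), so the static-level tree metrics select nothing
while the high-order pattern kernel recovers the groups at 85% LOO
accuracy with AUC 0.90 — the intended behavior: the discriminating signal
is visible only at the correlation-of-correlations level.

A shell workflow is available too:

```bash
homst simulate --n-per-group 20 --rois 10 --timepoints 120 --out cohort/
homst classify --cohort cohort/ --out results/
homst run --config run.yaml --out runs/r1   # end-to-end with manifest
```

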