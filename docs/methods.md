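# Methods

This note documents the modelling choices behind `homst`: what each stage
computes, the parameters that matter, what the synthetic cohorts do and
do not emulate, and where the design was genuinely open.

## Pipeline

Per subject (R ROIs × M time points):

1. **Sliding windows.** K = ⌊(M − N)/S⌋ + 1 windows of length N, stride
   S; window k covers columns [kS, kS + N). Defaults N = 90, S = 1, the
   standard operating point for ~240-volume resting-state scans. The
   count formula is the only reading of the window arithmetic consistent
   with those defaults; the floor handles non-divisible (M − N)/S.
2. **Low-order stack.** Pearson correlation of every ROI pair within
   each window (K symmetric R × R matrices, unit diagonal). Zero-variance
   subseries raise an error naming the window and ROI rather than
   emitting NaN — a silent NaN here would poison every downstream entry
   of the P × P high-order matrix.
3. **Correlation time series.** Pair (i, j), i < j, maps to pair-node
   q in fixed row-major order (0,1), (0,2), …, (R−2, R−1), so q has a
   stable anatomical meaning; row q of the P × K series matrix traces
   that pair across windows. P = R(R−1)/2 (4005 at R = 90).
4. **High-order network.** H[q, r] = Pearson correlation of series q
   and r. Requires K ≥ 3 (a length-2 correlation carries no usable
   variation; the N = M, S = 1 degenerate scheme is rejected). No
   Fisher z-transform is applied anywhere — correlations are used raw.
5. **Spanning tree.** Kruskal on edges sorted by descending signed
   weight (maximum-weight spanning tree), ties broken by
   (min node, max node) so identical inputs give identical trees on any
   platform. A config switch ranks by |weight| instead (off by default:
   the backbone is meant to keep the strongest *positive* couplings).
6. **Tree metrics.** Degree; eccentricity in hops; betweenness
   BC_i = Σ_{h≠i≠j} 1[i on h–j path] / ((n−1)(n−2)) over *ordered*
   pairs, so a star center attains exactly 1 — with unordered pairs the
   normalizer would cap the maximum at ½, contradicting "fraction of all
   shortest paths". On a tree each pair has exactly one path; the
   normalized betweenness of networkx computes this quantity and is
   verified against naive all-pairs path enumeration in the tests.
   Hop (unweighted) distances follow the spanning-tree connectome
   convention; a weighted variant was deliberately not added.
7. **Feature screening.** Two-sample Kolmogorov–Smirnov per
   (pair-node, metric) feature, asymptotic p-values (group sizes in the
   tens justify the asymptotic tail; scipy's exact mode remains
   available), Benjamini–Hochberg step-up at q = 0.05. Pair-nodes
   significant in ≥ 2 of the 3 metrics form the abnormal-connectivity
   report. The classifier consumes the per-metric BH mask (not the
   ≥ 2-rule subset), the less aggressive of the two readings.
8. **Pattern mining.** gSpan over each group's trees with node labels =
   pair-node identity. Identity labels make subgraph containment
   equal label-respecting edge-set inclusion (the fast path; the VF2
   monomorphism path covers the degree-label mode, and both are asserted
   to agree). Canonicalization is by minimum DFS code; candidates grow
   by rightmost-path extension; frequency ≥ min_fq prunes
   anti-monotonically; growth caps at 10 edges as a safety valve.
   Candidate pool for scoring = union of both groups' mined sets, with
   both frequencies recomputed on the full group lists;
   S = fq⁺ − fq⁻; balanced top-k per direction (k = 16), ties toward
   larger own-group frequency then canonical code order, with a warning
   on shortfall. Default thresholds 0.286 (group 1) / 0.211 (group 0).
9. **Kernels.** Each subject's graph for the WL subtree kernel is its
   tree restricted to the union of selected-pattern edges it actually
   contains — patterns are what discriminates, and whole 4005-node trees
   would drown 2k small patterns; a whole-tree mode exists. WL runs
   h = 3 refinement rounds (unspecified upstream; 2–4 is the customary
   range), stopping early when refinement no longer splits any label
   class across the cohort's disjoint union; iteration blocks are
   tagged so rounds contribute disjoint count features. Default initial
   labels are the node identities, consistent with mining; a
   degree-initialization flag reproduces the classic unlabeled-graph
   rule. The vector kernel is linear on per-feature standardized values
   (training-fold mean/sd only) — linear avoids a bandwidth
   hyperparameter at these sample sizes; RBF with the median heuristic
   is available. Both kernels are normalized to unit diagonal
   k* = k/√(k(x,x)k(y,y)) *before* combination; the convex combination
   is not re-normalized. A subject with an empty pattern graph has
   k(x,x) = 0 and receives an identity row (similar only to itself),
   with a logged warning.
10. **Classification.** Soft-margin SVM on the precomputed combined
    kernel. Class-balanced misclassification weights: leave-one-out
    folds are never exactly balanced, and an underfit SVM would
    otherwise drift toward the training majority — the opposite of the
    held-out class — biasing null accuracy below chance. Weight a on
    the grid {0, 0.1, …, 1.0} and cost on {0.1, 1, 10, 100} (no cost
    is specified upstream) are chosen by inner stratified-CV accuracy;
    ties resolve toward smaller a, then smaller cost. The a = 0 / a = 1
    endpoints reproduce the single-kernel baselines exactly.

## Evaluation protocol

The default is nested leave-one-out: feature selection, pattern mining
and kernel construction are re-run on each outer training fold, and the
inner grid search uses stratified folds of that training set. One
approximation is accepted: inner folds reuse the outer-training kernels
rather than re-mining patterns per inner fold, which would multiply the
cost ~fivefold while still touching no outer-test information.
`whole_sample` (or `--whole-sample`) instead performs whole-sample selection
and mining before a leave-one-out over the classifier only — the
optimistic protocol many published pipelines use; it is provided for
comparability and clearly flagged. When a training fold selects no
feature, the fold runs on the graph kernel alone (the weight grid
collapses), rather than inventing a vector kernel from unselected
features.

## Synthetic cohorts

`generate_cohort` draws each ROI as an independent standard-normal
source, then, for each designated effect pair (i, j), mixes source i
into ROI j with weight w(t), keeping unit variance, plus additive
Gaussian observation noise (sd 0.2 by default). Group 1 uses
w(t) = (e/2)(1 + sin(2πt/M + φ)) — one slow cycle per scan, amplitude
e = `effect_size`, a single random phase φ per subject shared by all
effect pairs so their correlation series co-fluctuate. Group 0 holds
w at the sinusoid's mean e/2. Both groups therefore share the *average*
coupling; only its dynamics — exactly what the high-order network
measures — differ, so the class signal deliberately bypasses the static
(low-order) level. At e = 0 the two groups are draws from one process.

What this does not emulate: autocorrelated BOLD-like spectra,
physiological/motion confounds, inter-subject anatomical variability,
heavy-tailed noise, or any claim about real clinical dynamics. Passing
tests demonstrate that the implementation recovers dynamics-borne group
structure at realistic noise levels, not that it would reach any
particular accuracy on clinical data.

Reference test scale: R = 10, M = 120, 20 + 20 subjects, window N = 30,
S = 1 (window shorter than the modulation period, long enough for stable
windowed correlations — the same N:M logic as 90:238 at full scale), and
a fixed seed; the full R = 90, M = 238 scale is exercised for the
structural checks (4005 pair-nodes, 4004 tree edges). Null-calibration
checks use R = 6, M = 60, 6 + 6 subjects so that twenty full
nested-LOO pipelines run in about a minute.

## Numerical and degenerate-input conventions

* Correlations are clipped to [−1, 1] after computation; matrices get
  exact unit diagonals.
* Kernel PSD assertions tolerate eigenvalues ≥ −1e−8; the weight simplex
  is enforced to 1e−12.
* Confusion metrics threshold decision scores at 0; AUC is the
  trapezoidal area under the full ROC (ties give 0.5).
* Betweenness requires n ≥ 3 (the (n−1)(n−2) normalizer); spanning
  trees require connected input; Relief requires ≥ 2 subjects per class.
* Relief scales features to [0, 1] range before distance computations
  (the classic normalization); every subject is visited once in seeded
  random order with one nearest hit and miss.

## Known limitations

* Mining cost grows with tree similarity within a group; the 10-edge
  pattern cap bounds the worst case but very homogeneous cohorts may
  still mine slowly at P = 4005.
* The KS screen treats features independently; spatially correlated
  tree metrics make BH conservative rather than invalid.
* Leave-one-out accuracy has high variance at small n; the report's
  per-fold parameter choices are logged for inspection.
* With identity node labels, patterns never generalize across different
  pair-nodes; the degree-label mode trades anatomical interpretability
  for topological generality.
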