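# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of the pipeline. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## Sliding-window dFC

The estimator is the plain rectangular-window Pearson correlation: no taper,
no demeaning beyond Pearson's internal centering, no shrinkage of the window
covariance. Window length is specified in seconds (default **40 s**) and
converted to TRs by rounding, because acquisitions differ in TR (a 0.72 s TR
gives L = 56; a 2 s TR gives L = 20); the slide step is **5 TRs**. Incomplete
trailing windows are dropped (floor rule) so every column of S has the same
sampling variance. Correlations are clipped at |r| = 1 − 10⁻⁷ before the
Fisher transform, which is undefined at |r| = 1; a zero-variance ROI inside a
window is an error by default (it names the ROI and window) with an opt-in
imputation to z = 0.

Rows of S are **not** row-standardized before embedding; a connection's mean
coupling level and its fluctuation both carry signal, and removing them is
left to the caller.

The canonical connection order is the row-major upper triangle
(0,1), (0,2), …, (0,R−1), (1,2), …, fixed once and used by every stage (dFC
rows, CCP labels, coreness vectors, statistical maps, matrix rearrangement).
Indices are 0-based internally; 1-based ROI ids in files are mapped on read.

## Intrinsic dimension

The Levina–Bickel estimator is used in its published (1/(k−1)) form with
T_k the distance to the k-th neighbor. Two properties matter in practice:

* It is scale-invariant (only distance ratios enter), which the suite
  asserts exactly.
* It carries a known multiplicative bias of roughly (k−1)/(k−2) on
  full-dimensional clouds at moderate k. On uniform d-dimensional hyperplane
  samples (n = 5000, k = 12) the rounded estimate still recovers
  d ∈ {1, 2, 3, 5}; on an isotropic Gaussian in ℝ⁵ the raw estimate is ≈ 5.6,
  i.e. correct up to that bias band. No bias correction is applied because
  the downstream decision (an integer d shared by the embedding and the CCP
  count) tolerates it on ray-structured dFC clouds, and k-range averaging
  (`k_range=(6, 12)`) is available to smooth the k-sensitivity.

A `tk_sum` switch replaces T_k with Σⱼ Tⱼ. It exists for literal fidelity to
one textual description of the estimator; it is not scale-consistent as a
dimension estimator (the suite demonstrates it shrinks estimates on
hyperplane fixtures) and is off by default.

Duplicate points would contribute log(T_k/0) terms; the cloud is
deduplicated before neighbor search, so a dataset with every point doubled
yields the identical estimate.

Neighborhood size defaults to the LLE neighbor count (k = 12).

## Locally linear embedding

Authored in full rather than delegated, because the downstream contract is
specific: W rows sum to one (≤ 10⁻¹⁰), Σᵢvᵢ = 0, Σᵢvᵢvᵢᵀ = n·I (the
eigenvectors are scaled by √n), and a deterministic sign convention (each
column's largest-magnitude entry is positive) so that cosine k-means is
reproducible run to run. `sklearn`'s implementation — which normalizes
differently and fixes no signs — serves as an independent cross-check in the
tests (embedding coordinates correlate > 0.85 on a curved-sheet fixture).

Numerical conventions:

* **Neighbor ties** break toward the lower index (stable argsort on exact
  distances).
* **Weight solve.** The local Gram system G w = 1 (rows then normalized) is
  regularized with Tikhonov reg = 10⁻³·trace(G)/k only when k exceeds the
  ambient dimension, where G is structurally rank-deficient and the
  regularizer is what selects a stable, geometry-respecting solution (the
  classic LLE conditioning rule). With k ≤ ambient, a singular G (points on
  an exact low-dimensional plane) is solved through the least-squares KKT
  system instead, recovering the exact zero-error reconstruction: planar
  fixtures embed with cost Ψ ≈ 10⁻¹³ rather than the ≈ 10⁻⁶ a blanket
  regularizer would leave. A point coinciding with a neighbor is
  reconstructed exactly by splitting the weight over its duplicates.
* **Constant mode.** The all-ones vector is always a 0-eigenvector of
  M = (I−W)ᵀ(I−W). Below n = 2000 the dense solver deflates it by adding
  σ·(11ᵀ/n) with σ above a Gershgorin bound of the spectrum, which remains
  correct when the null space is degenerate; at or above n = 2000 a
  shift-invert Lanczos solver takes the bottom d+1 vectors and the constant
  direction is rotated out by a Householder reflection.
* k defaults to 12; k ≥ d+1 is enforced.

## CCP clustering

Spherical k-means on unit-normalized embedding rows: distance
1 − cos(angle), centroid = normalized member mean, best of n_init = 20
k-means++-style seeded restarts, empty clusters re-seeded at the worst-fit
point. The objective is asserted non-increasing every iteration. Cluster ids
are reported in descending size order, a stable default identity; matching
across models is an explicit operation (`match_ccps`) returning the d×d SOR
matrix and the assignment-optimal pairing, since the natural reference
ordering depends on the study design. SOR is intersection-over-union of the
two connection sets. The cluster count equals the embedding dimension d —
one CCP per embedding coordinate.

## Core-periphery scores

The kNN graph over embedded connections uses union symmetrization (an edge
if either endpoint lists the other) and unweighted 0/1 adjacency, because
the γ profile counts links; k_graph defaults to the LLE k. The nonlinear
spectral iteration ascends f_α(x) = Σ Aᵢⱼ‖(xᵢ,xⱼ)‖_α with α = 10 — large α
approximates the max-norm objective that rewards every edge touching at
least one high-score node. The fixed-point map is 0-homogeneous, so iterates
are max-normalized for floating-point stability; the objective trace is kept
and asserted monotone. Convergence uses the Euclidean relative-change rule
with tol = 10⁻⁶, max 1000 iterations (warning + last iterate beyond that).
Disconnected graphs — common for sparse kNN graphs over well-separated
arms — are scored per connected component with a warning and normalized
globally; isolated vertices get a floor score so c stays strictly positive.

At α = 10 the optimum on a star graph puts essentially all mass on the hub
(the leaves' scores collapse toward zero); a grid search over the symmetric
two-parameter family confirms the iteration lands at the brute-force
maximizer's corner.

## Statistics

* **eta²** compares two maps by within-position vs total variance. Symmetric
  square inputs are compared on their vectorized upper triangles so mirrored
  cells are not double-counted. It is 1 only for identical maps and is
  invariant to a common additive shift.
* **Family-wise error** uses Holm step-down by default (uniformly more
  powerful than Bonferroni at identical FWER; Bonferroni available as an
  option). Zero-variance difference features get t = 0, p = 1 with a
  warning.
* **Permutation tests** use the add-one estimator
  p = (1 + #{|T_perm| ≥ |T_obs|})/(B+1), B = 1000 by default, so p is never
  zero and the test is valid (conservative). Paired designs flip
  within-subject condition signs instead of shuffling group labels.

## Classification

Per-fold pipeline: two-sample t-test screen at p < 0.05 (uncorrected — the
screen is a filter, not an inference), train-fold standardization, linear
SVM with C = 1. Nothing is ever fit on held-out samples; the suite includes
an explicit leakage guard (corrupting test rows cannot change fold-wise
feature selection). If no feature passes the screen, the 50 smallest-p
features are used with a warning. LOOCV is deterministic and therefore run
once; repetition ("× 100") applies to the stratified k-fold scheme, which
reshuffles folds per repeat from the seed. One-vs-rest multiclass trains one
screened classifier per class and predicts by maximal decision value.

## Synthetic data: what it does and does not emulate

The generators are pure functions of (parameters, seed); one global seed
expands into named substreams so adding a call never shifts another
generator's draws. Planted structure is always returned for scoring.

* `gen_dfc_direct` plants M prototype trajectories (near-orthogonal
  sinusoids by default) with a per-connection coupling strength uniform in
  ±25% around the base amplitude 0.8 — connections expressing a shared
  pattern at different strengths, so each module traces a ray, the geometry
  the angle-based clustering targets. Noise is i.i.d. Gaussian at
  sd = amplitude/snr; rows are tanh-squashed into valid correlations then
  Fisher-z transformed. Default study conditions: M = 6, n = 435
  (a 30-ROI connectome), D = 120 windows, snr = 3.
* `gen_roi_timeseries_tv` draws independent Gaussians with a block
  correlation structure whose between-block coupling follows a slow
  sinusoid in [0, 0.8] (period defaulting to a third of the scan), with a
  nearest-positive-definite projection when block assembly requires it.
* `gen_core_periphery_graph` is a three-probability stochastic block model
  (core-core, core-periphery, periphery-periphery).
* `gen_two_class_coreness` plants a mean shift of `effect_size` standard
  deviations on a designated feature subset.

None of these emulate hemodynamic response shapes, autocorrelated scanner
noise, motion artifacts, inter-subject variability or the spatial covariance
of real connectomes. Passing the recovery suites therefore demonstrates the
correctness of the algorithms under their own assumptions — planted
structure of the stated kind, at the stated noise level — not performance on
real fMRI.

## Problem sizes

The verification suites use a 30-ROI / 435-connection scale (windows D in
the tens to low hundreds), 5000-point clouds for dimension recovery and
100-node graphs for core recovery; these sizes give stable statistics while
keeping the full suite and the acceptance script each under a minute of CPU.
The implementation itself is written for the 12,720-connection scale (sparse
weight matrices, chunked neighbor search, Lanczos eigensolver above
n = 2000).

## Known limitations

* Tapered windows, DCC/GARCH-style estimators and phase-synchrony dFC are
  out of scope.
* The MLE dimension estimate on noisy dFC rows reflects local noise
  dimensionality when the window noise is isotropic and large relative to
  arm curvature; at low snr, fixing d from domain knowledge (or the CCP
  count) is the realistic path, and the CLI supports an explicit `--d`.
* Cosine k-means assumes arms radiate from the origin; coupling patterns
  that differ only in radius are one CCP by construction.
* Per-component NSM scores are comparable within a component; the global
  max-normalization makes cross-component comparisons ordinal only.
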