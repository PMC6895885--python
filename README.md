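# dfcmanifold

Manifold learning of dynamic functional connectivity (dFC) for brain-network
analysis: identify **Consistent Coupling Patterns (CCPs)** — groups of
region-pair connections whose windowed-correlation time courses co-fluctuate —
and quantify each connection's **core-periphery role** in the resulting
manifold, with the statistics and classification protocol needed to compare
conditions (rest vs task, rested vs sleep-deprived).

## Who this is for

Researchers with preprocessed, ROI-averaged fMRI time series (any atlas; the
classic case is 160 ROIs grouped into six functional networks) who want a
nonlinear, connection-level decomposition of time-varying connectivity instead
of linear PCA/ICA state analyses.

## Method

1. **Sliding-window dFC.** A rectangular window of 40 s (converted to
   L = round(40/TR) TRs) slides in steps of 5 TRs. Each window's R×R Pearson
   correlation matrix is vectorized over its upper triangle
   (n = R(R−1)/2 pairs; 12,720 for R = 160) and Fisher-z transformed,
   giving S ∈ ℝ^(n×D), one z-correlation trajectory per connection.
2. **Intrinsic dimension.** The Levina–Bickel maximum-likelihood estimator
   d̂_k(sᵢ) = [(1/(k−1)) Σ_{j<k} log(T_k/T_j)]⁻¹, averaged over connections,
   sets the embedding dimension d (and the CCP count).
3. **Locally linear embedding.** Each row sᵢ is reconstructed from its k
   nearest neighbors with weights wᵢⱼ minimizing ε(W) = Σᵢ‖sᵢ − Σⱼ wᵢⱼsⱼ‖²
   subject to Σⱼ wᵢⱼ = 1; coordinates V ∈ ℝ^(n×d) minimize
   Ψ(V) = Σᵢ‖vᵢ − Σⱼ wᵢⱼvⱼ‖² under Σᵢvᵢ = 0 and Σᵢvᵢvᵢᵀ = n·I — the bottom
   non-constant eigenvectors of (I−W)ᵀ(I−W).
4. **CCPs.** The embedding spreads connections along "arms" through the
   origin; spherical k-means (distance = 1 − cosine of the angle to the
   origin) with K = d separates the arms. CCPs from two models are matched
   by their spatial overlap rate SOR = |A∩B|/|A∪B| with optimal assignment.
5. **Core-periphery.** The embedding's union-symmetrized kNN graph is scored
   by a nonlinear spectral method: power iteration on the gradient map of
   f_α(x) = Σᵢⱼ Aᵢⱼ(xᵢ^α + xⱼ^α)^(1/α) (α = 10), stopping when
   ‖x_k − x_{k+1}‖/‖x_{k+1}‖ < 10⁻⁶; coreness c = x/max(x) ∈ (0,1]. The
   profile γ_k (periphery-periphery links over periphery-all links under the
   ascending-score ordering) diagnoses the structure.
6. **Statistics & classification.** eta² similarity between core-quality
   maps; paired t-tests with Holm FWER control; 1000-draw label-permutation
   tests; per-fold t-screened linear SVM with LOOCV / repeated stratified
   10-fold / one-vs-rest protocols.

## Worked example

Synthetic dFC with six planted connection modules (435 connections × 120
windows, prototype-to-noise ratio 3), embedded and clustered end to end:

```python
import numpy as np
import dfcmanifold as dm
from sklearn.metrics import adjusted_rand_score

spec = dm.SyntheticSpec(seed=7, M=6, n=435, D=120, snr=3.0)
S, planted, _ = dm.gen_dfc_direct(spec)

emb = dm.lle(S, k=12, d=6)
labeling = dm.cosine_kmeans(emb.V, d=6, seed=0)
print("CCP sizes:", np.bincount(labeling.labels).tolist())
print("ARI vs planted modules:",
      round(adjusted_rand_score(planted, labeling.labels), 2))

graph = dm.knn_adjacency(emb.V, k_graph=12)
core = dm.nsm_coreness(graph)
gamma = dm.gamma_profile(core.c, graph)
print("converged in", core.iterations, "iterations;",
      "gamma at n/2 =", round(gamma[len(gamma) // 2], 3))
```

prints

```
CCP sizes: [73, 73, 73, 72, 72, 72]
ARI vs planted modules: 1.0
converged in 122 iterations; gamma at n/2 = 0.0
```

All six planted modules are recovered exactly (adjusted Rand index 1.0), and
γ = 0 at half the ranking means the lower-scored half of the connections
carries no internal edges — a clean core-periphery split. At this noise level
the local MLE dimension of the raw rows reflects the isotropic window noise
rather than the six arms, so the example fixes d = M = 6 explicitly; on real
data the averaged estimate is used directly (`dm.mle_dim_dataset(S, k=12).d`).

The same pipeline is scriptable from the shell:

```bash
dfcmanifold simulate --mode timeseries --rois 30 --timepoints 200 --tr 2.0 --out sim/
dfcmanifold run-all --timeseries sim/timeseries.tsv --k 12 --out run/
```

Every output directory carries a `manifest.json` with parameters, input
digests and the package version, so runs are exactly reproducible.

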