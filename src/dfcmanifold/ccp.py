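"""Consistent Coupling Patterns: angle-based k-means on the embedding.

The LLE embedding of dFC spreads connections along "arms" radiating from
the origin; connections sharing an arm co-fluctuate. Clustering by the
cosine of the angle to the origin (spherical k-means) separates the arms
into d CCPs, where d is the embedding dimension — one cluster per
embedding coordinate.

CCPs from two models (two subjects, two conditions, two datasets) are
matched by their spatial overlap rate, SOR = |A intersect B| / |A union B|
(Jaccard index over connection sets), with the optimal one-to-one pairing
found by the assignment algorithm.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core_io import Atlas, PairIndex, ValidationError

__all__ = ["CcpLabeling", "SorMatrix", "cosine_kmeans", "sor", "match_ccps",
           "ccp_to_matrix"]


@dataclasses.dataclass
class CcpLabeling:
    """Partition of the n connections into d CCPs.

    Cluster ids are 0..d-1 in descending cluster-size order; centroids are
    unit vectors in embedding space.
    """

    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    n_iter: int
    seed: int

    @property
    def d(self) -> int:
        return self.centroids.shape[0]

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


@dataclasses.dataclass
class SorMatrix:
    """Pairwise SOR between two labelings' CCPs plus the optimal matching."""

    sor: np.ndarray                      # (dA, dB)
    matching: list[tuple[int, int]]      # (cluster in A, cluster in B)
    relabeled_b: np.ndarray              # labels of B renamed to match A

    @property
    def mean_matched_sor(self) -> float:
        return float(np.mean([self.sor[i, j] for i, j in self.matching]))


def _unit_rows(V: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(V, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(f"{what}: row {zero[0]} is all-zero; angle to origin undefined")
    return V / norms[:, None]


def _kmeanspp_init(U: np.ndarray, d: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding with cosine distance on unit vectors."""
    n = U.shape[0]
    centroids = np.empty((d, U.shape[1]))
    centroids[0] = U[rng.integers(n)]
    dist = 1.0 - U @ centroids[0]
    np.clip(dist, 0, None, out=dist)
    for c in range(1, d):
        total = dist.sum()
        if total <= 0:
            centroids[c] = U[rng.integers(n)]
        else:
            centroids[c] = U[rng.choice(n, p=dist / total)]
        dist = np.minimum(dist, np.clip(1.0 - U @ centroids[c], 0, None))
    return centroids


def cosine_kmeans(V: np.ndarray, d: int, seed: int = 0, n_init: int = 20,
                  max_iter: int = 300, tol: float = 1e-9) -> CcpLabeling:
    """Spherical k-means: distance = 1 - cos(angle between point and centroid).

    Points are projected to the unit sphere (assignments are therefore
    invariant to positive rescaling of any point); centroids are normalized
    means of their members. Best of ``n_init`` seeded restarts. An emptied
    cluster is re-seeded at the worst-fit point. The objective (sum of
    cosine distances to assigned centroids) never increases across
    iterations.
    """
    V = np.asarray(V, dtype=float)
    if d < 2:
        raise ValidationError(f"need d >= 2 clusters, got {d}")
    if V.shape[0] < d:
        raise ValidationError(f"fewer points ({V.shape[0]}) than clusters ({d})")
    U = _unit_rows(V, "cosine_kmeans")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centroids = _kmeanspp_init(U, d, rng)
        prev_obj = np.inf
        for it in range(1, max_iter + 1):
            sim = U @ centroids.T                    # cosine similarity
            labels = np.argmax(sim, axis=1)
            obj = float(np.sum(1.0 - sim[np.arange(U.shape[0]), labels]))
            # update step
            new_centroids = np.empty_like(centroids)
            for c in range(d):
                members = labels == c
                if not members.any():
                    worst = np.argmin(sim[np.arange(U.shape[0]), labels])
                    new_centroids[c] = U[worst]
                    continue
                m = U[members].mean(axis=0)
                nm = np.linalg.norm(m)
                new_centroids[c] = m / nm if nm > 0 else centroids[c]
            assert obj <= prev_obj + 1e-9, "cosine k-means objective increased"
            if prev_obj - obj < tol:
                centroids = new_centroids
                break
            prev_obj = obj
            centroids = new_centroids
        if best is None or obj < best[0]:
            best = (obj, labels.copy(), centroids.copy(), it)
    obj, labels, centroids, n_iter = best
    # stable identity: rename clusters in descending size order
    sizes = np.bincount(labels, minlength=d)
    order = np.argsort(-sizes, kind="stable")
    rename = np.empty(d, dtype=int)
    rename[order] = np.arange(d)
    return CcpLabeling(labels=rename[labels], centroids=centroids[order],
                       inertia=obj, n_iter=n_iter, seed=seed)


def sor(set_a, set_b) -> float:
    """Spatial overlap rate between two connection sets: |A∩B| / |A∪B|."""
    A, B = set(set_a), set(set_b)
    union = A | B
    if not union:
        raise ValidationError("SOR undefined: both connection sets empty")
    return len(A & B) / len(union)


def match_ccps(labeling_a: CcpLabeling, labeling_b: CcpLabeling) -> SorMatrix:
    """Optimal one-to-one CCP matching between two labelings by total SOR."""
    if labeling_a.labels.shape != labeling_b.labels.shape:
        raise ValidationError("labelings cover different pair universes")
    dA, dB = labeling_a.d, labeling_b.d
    if dA != dB:
        import warnings
        warnings.warn(f"labelings have different CCP counts ({dA} vs {dB}); "
                      f"matching the first min(dA, dB)", RuntimeWarning, stacklevel=2)
    S = np.zeros((dA, dB))
    for i in range(dA):
        mi = set(labeling_a.members(i).tolist())
        for j in range(dB):
            mj = set(labeling_b.members(j).tolist())
            if mi or mj:
                S[i, j] = len(mi & mj) / len(mi | mj)
    rows, cols = linear_sum_assignment(-S)
    matching = list(zip(rows.tolist(), cols.tolist()))
    rename = np.empty(dB, dtype=int)
    matched_b = {j: i for i, j in matching}
    spare = iter(sorted(set(range(dA + dB)) - set(matched_b.values())))
    for j in range(dB):
        rename[j] = matched_b[j] if j in matched_b else next(spare)
    return SorMatrix(sor=S, matching=matching, relabeled_b=rename[labeling_b.labels])


def ccp_to_matrix(labeling: CcpLabeling, pair_index: PairIndex,
                  atlas: Atlas | None = None) -> np.ndarray:
    """Rearrange CCP labels into a symmetric R x R categorical matrix.

    Diagonal entries are -1 (absent). When an atlas is given, rows/columns
    are permuted into network-block order for display.
    """
    if labeling.labels.shape[0] != pair_index.n:
        raise ValidationError(
            f"{labeling.labels.shape[0]} labels for {pair_index.n} pairs"
        )
    M = pair_index.vector_to_matrix(labeling.labels.astype(float), diagonal=-1.0)
    if atlas is not None:
        if atlas.R != pair_index.R:
            raise ValidationError(f"atlas has {atlas.R} ROIs, pair index {pair_index.R}")
        order = atlas.network_sort_order()
        M = M[np.ix_(order, order)]
    return M
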