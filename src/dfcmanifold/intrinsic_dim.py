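"""Maximum-likelihood intrinsic dimension of the dFC point cloud.

The Levina–Bickel estimator models nearest-neighbor distances as arrivals
of a Poisson process on the manifold. For one point with sorted neighbor
distances T_1 <= ... <= T_k the local estimate is

    d_hat_k(x) = [ (1/(k-1)) * sum_{j=1}^{k-1} log(T_k / T_j) ]^(-1)

and the dataset estimate is the average of the local estimates over all
points. Only distance *ratios* enter, so the estimate is invariant to a
global rescaling of the cloud. The rounded average fixes both the LLE
embedding dimension d and the CCP count downstream.

A ``tk_sum`` compatibility switch replaces T_k with sum_j T_j in the
ratio; it is a literal-fidelity variant, not the default, because it is
not scale-consistent as a dimension estimator (see the methods note).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .core_io import NumericError, ValidationError

__all__ = ["DimEstimate", "mle_dim_point", "mle_dim_dataset"]


@dataclasses.dataclass
class DimEstimate:
    """Dataset intrinsic-dimension estimate."""

    d_hat_real: float           # averaged estimator
    d: int                      # rounded, used downstream (>= 1)
    k_range: tuple[int, ...]    # neighborhood sizes averaged over
    point_estimates: np.ndarray  # per-point estimates at the last k


def mle_dim_point(distances: np.ndarray, ambient_dim: int | None = None,
                  tk_sum: bool = False) -> float:
    """Local MLE dimension from one point's sorted k-NN distances.

    ``distances`` are the Euclidean distances to the k nearest neighbors,
    ascending and strictly positive (exclude duplicates beforehand). When
    all k-1 log ratios vanish (equidistant neighbors) the estimate
    diverges; it is capped at ``ambient_dim`` (or +inf) with a warning.
    """
    T = np.asarray(distances, dtype=float)
    k = T.size
    if k < 3:
        raise ValidationError(f"need k >= 3 neighbor distances, got {k}")
    if np.any(T <= 0):
        raise ValidationError("neighbor distances must be strictly positive")
    if np.any(np.diff(T) < 0):
        raise ValidationError("neighbor distances must be sorted ascending")
    Tk = T.sum() if tk_sum else T[-1]
    denom = np.log(Tk / T[:-1]).sum() / (k - 1)
    if denom <= 0:
        cap = float(ambient_dim) if ambient_dim is not None else np.inf
        warnings.warn(
            "degenerate neighbor spacing (all log distance ratios zero); "
            f"capping local dimension estimate at {cap}",
            RuntimeWarning, stacklevel=2,
        )
        return cap
    return 1.0 / denom


def mle_dim_dataset(X: np.ndarray, k: int = 12,
                    k_range: tuple[int, int] | None = None,
                    tk_sum: bool = False) -> DimEstimate:
    """Averaged MLE intrinsic dimension of a point cloud (rows = points).

    Duplicate points (zero neighbor distances) are excluded from each
    neighborhood. With ``k_range=(k_lo, k_hi)`` the dataset estimate is the
    mean of the per-k averages over that inclusive range, smoothing the
    estimator's k-sensitivity.
    """
    X = np.asarray(X, dtype=float)
    ks = tuple(range(k_range[0], k_range[1] + 1)) if k_range is not None else (k,)
    if min(ks) < 3:
        raise ValidationError(f"need k >= 3, got {min(ks)}")
    k_max = max(ks)

    # Duplicated points carry zero distances that break the log ratios;
    # the cloud is deduplicated so every neighborhood is well defined and a
    # duplicated dataset yields the identical estimate.
    Xu, inverse = np.unique(X, axis=0, return_inverse=True)
    n = Xu.shape[0]
    ambient = Xu.shape[1]
    if Xu.shape[0] < X.shape[0]:
        warnings.warn(
            f"excluded {X.shape[0] - Xu.shape[0]} duplicate points before "
            "dimension estimation",
            RuntimeWarning, stacklevel=2,
        )
    if n <= k_max:
        raise ValidationError(f"need more distinct points than neighbors: "
                              f"n={n}, k={k_max}")
    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(Xu)
    dist, _ = nn.kneighbors(Xu)
    dist = dist[:, 1:]  # drop self

    per_k_means = []
    point_estimates = None
    for kk in ks:
        ests = np.full(n, np.nan)
        for i in range(n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ests[i] = mle_dim_point(dist[i, :kk], ambient_dim=ambient,
                                        tk_sum=tk_sum)
        finite = ests[np.isfinite(ests)]
        if finite.size < 10:
            raise NumericError(
                f"only {finite.size} finite local dimension estimates at k={kk}; "
                "dataset too degenerate to estimate dimension"
            )
        per_k_means.append(finite.mean())
        point_estimates = ests
    d_hat = float(np.mean(per_k_means))
    return DimEstimate(
        d_hat_real=d_hat,
        d=max(1, int(round(d_hat))),
        k_range=ks,
        point_estimates=point_estimates[inverse],
    )
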