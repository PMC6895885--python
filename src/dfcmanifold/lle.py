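"""Locally linear embedding of the dFC connection cloud.

Three steps map the n connection rows of S (points in R^D) to coordinates
V in R^d:

1. k nearest neighbors of each point by Euclidean distance (ties broken
   toward the lower index, self excluded).
2. Reconstruction weights: per point, the constrained least squares
   min ||s_i - sum_j w_ij s_j||^2 subject to sum_j w_ij = 1, solved through
   the local Gram system with Tikhonov conditioning. The sum-to-one
   constraint makes the weights invariant to translations; using only
   difference vectors makes them invariant to rotations and rescalings.
3. Coordinates: minimize Psi(V) = sum_i ||v_i - sum_j w_ij v_j||^2 with the
   weights fixed, under sum_i v_i = 0 and sum_i v_i v_i^T = n * I. The
   minimizer is given by the bottom d+1 eigenvectors of
   M = (I - W)^T (I - W); the constant eigenvector (eigenvalue ~ 0) is
   discarded and the rest are scaled by sqrt(n) to satisfy the covariance
   constraint. Eigenvector signs are arbitrary, so each column is flipped
   to make its largest-magnitude entry positive — downstream cosine
   k-means then sees a reproducible embedding.

A dense eigensolver is used below n = 2000 (it doubles as the correctness
oracle); above that, shift-invert sparse Lanczos.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core_io import NumericError, ValidationError

DENSE_EIG_THRESHOLD = 2000
WEIGHT_REG = 1e-3  # Tikhonov: reg = WEIGHT_REG * trace(G) / k

__all__ = ["EmbeddingResult", "knn_neighbors", "reconstruction_weights",
           "embed_coordinates", "lle"]


@dataclasses.dataclass
class EmbeddingResult:
    """LLE output: coordinates plus the structure that produced them."""

    V: np.ndarray                 # (n, d), sum v_i = 0, sum v_i v_i^T = n I
    k: int
    W: sp.csr_matrix              # (n, n) reconstruction weights, rows sum to 1
    neighbors: np.ndarray         # (n, k) neighbor indices
    reconstruction_error: float   # eps(W)
    embedding_cost: float         # Psi(V)
    eigenvalues: np.ndarray       # the d bottom non-constant eigenvalues of M

    @property
    def n(self) -> int:
        return self.V.shape[0]

    @property
    def d(self) -> int:
        return self.V.shape[1]


def knn_neighbors(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of each point's k nearest neighbors (Euclidean, self excluded).

    Exact ties are broken toward the lower index. Duplicated points appear
    as zero-distance neighbors.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than n={n}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    sq = np.einsum("ij,ij->i", X, X)
    neighbors = np.empty((n, k), dtype=np.intp)
    chunk = max(1, min(n, int(2e7 // max(n, 1))))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        # squared Euclidean distances, clipped against negative round-off
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * (X[lo:hi] @ X.T)
        np.clip(d2, 0, None, out=d2)
        d2[np.arange(lo, hi) - lo, np.arange(lo, hi)] = np.inf  # exclude self
        # stable sort on distance => ties resolve to the lower index
        order = np.argsort(d2, axis=1, kind="stable")
        neighbors[lo:hi] = order[:, :k]
    return neighbors


def _solve_constrained_weights(G: np.ndarray, k: int, ambient: int,
                               i: int) -> np.ndarray:
    """Solve min w'Gw s.t. sum(w) = 1 for one local Gram matrix.

    Standard LLE conditioning: when k exceeds the ambient dimension the
    Gram matrix is structurally rank-deficient and Tikhonov regularization
    reg = 1e-3 trace(G)/k selects a stable solution. Otherwise the system
    is solved exactly — directly for nonsingular G, through the
    least-squares KKT system for singular G (e.g. neighborhoods on an
    exact low-dimensional plane), which recovers the exact zero-error
    reconstruction when one exists.
    """
    trace = float(np.trace(G))
    scale = trace / k if trace > 0 else 1.0
    if k <= ambient:
        if np.linalg.eigvalsh(G)[0] > 1e-10 * scale:  # numerically nonsingular
            w = np.linalg.solve(G, np.ones(k))
            s = w.sum()
            if np.isfinite(s) and s != 0:
                return w / s
        # singular: KKT [2G 1; 1' 0] [w; nu] = [0; 1] by least squares
        KKT = np.zeros((k + 1, k + 1))
        KKT[:k, :k] = 2.0 * G
        KKT[:k, k] = 1.0
        KKT[k, :k] = 1.0
        rhs = np.zeros(k + 1)
        rhs[k] = 1.0
        w = np.linalg.lstsq(KKT, rhs, rcond=None)[0][:k]
        s = w.sum()
        if np.isfinite(s) and abs(s - 1.0) < 1e-6 and np.linalg.norm(w) < 1e6:
            return w / s
    # Tikhonov-conditioned solve
    Greg = G + np.eye(k) * (WEIGHT_REG * scale)
    w = np.linalg.solve(Greg, np.ones(k))
    s = w.sum()
    if s == 0 or not np.isfinite(s):
        raise NumericError(f"degenerate reconstruction weights at point {i}")
    return w / s


def reconstruction_weights(X: np.ndarray, neighbors: np.ndarray,
                           ) -> tuple[sp.csr_matrix, float]:
    """Constrained least-squares reconstruction weights and eps(W).

    Per point the local Gram matrix G_ab = (s_i - s_a) . (s_i - s_b) is
    conditioned with Tikhonov regularization reg = 1e-3 * trace(G) / k and
    the system G w = 1 is solved, then w is normalized to sum to one.
    Zero-distance (duplicate) neighbors reconstruct the point exactly and
    receive the full weight, split equally among them.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = neighbors.shape[1]
    rows = np.repeat(np.arange(n), k)
    cols = neighbors.ravel()
    vals = np.empty(n * k)
    eps_total = 0.0
    for i in range(n):
        Z = X[neighbors[i]] - X[i]           # (k, D) difference vectors
        G = Z @ Z.T
        if not np.all(np.isfinite(G)):
            raise NumericError(f"non-finite local Gram matrix at point {i}")
        dup = np.flatnonzero(np.einsum("ij,ij->i", Z, Z) == 0.0)
        if dup.size:
            w = np.zeros(k)
            w[dup] = 1.0 / dup.size          # exact reconstruction
        else:
            w = _solve_constrained_weights(G, k, X.shape[1], i)
        vals[i * k:(i + 1) * k] = w
        resid = X[i] - w @ X[neighbors[i]]
        eps_total += float(resid @ resid)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return W, eps_total


def embed_coordinates(W: sp.spmatrix, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Bottom-eigenvector embedding: V (n x d) and its d eigenvalues.

    Forms M = (I - W)^T (I - W), takes the d+1 smallest eigenpairs, drops
    the constant one and rescales by sqrt(n) so sum_i v_i v_i^T = n I.
    """
    n = W.shape[0]
    if not (0 < d < n - 1):
        raise ValidationError(f"need 0 < d < n-1, got d={d}, n={n}")
    IW = sp.identity(n, format="csr") - sp.csr_matrix(W)
    M = (IW.T @ IW).tocsc()
    # The constant vector is always a 0-eigenvector of M (W rows sum to 1);
    # the embedding must exclude it. Dense path: deflate it by adding
    # sigma * (1 1^T / n) with sigma above the spectrum, so the bottom d
    # eigenvectors are automatically orthogonal to the constant — robust
    # even when the null space is degenerate (exactly planar data). Sparse
    # path: shift-invert Lanczos for the bottom d+1, then rotate the
    # constant direction out of that subspace.
    if n < DENSE_EIG_THRESHOLD:
        Md = M.toarray()
        sigma = float(np.abs(Md).sum(axis=1).max()) + 1.0  # Gershgorin bound
        Md += sigma / n
        evals, evecs = np.linalg.eigh(Md)
        V = evecs[:, :d]
        evals = evals[:d]
    else:
        try:
            evals, evecs = spla.eigsh(M, k=d + 1, sigma=0.0, which="LM")
        except Exception as exc:  # ARPACK non-convergence or factorization failure
            raise NumericError(
                f"sparse eigensolver failed ({exc}); consider raising k"
            ) from exc
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
        c0 = np.full(n, 1.0 / np.sqrt(n))
        g = evecs.T @ c0
        if np.linalg.norm(g) > 0.99:
            u = g / np.linalg.norm(g)
            u[0] -= 1.0
            nu = np.linalg.norm(u)
            H = (np.eye(d + 1) if nu == 0
                 else np.eye(d + 1) - 2.0 * np.outer(u, u) / nu**2)
            V = (evecs @ H)[:, 1:]
            evals = np.einsum("ij,ij->j", V, (M @ V))  # Rayleigh quotients
        else:  # constant mode missed (fragmented graph): drop vector 0
            evals, V = evals[1:], evecs[:, 1:]
    V = V * np.sqrt(n)
    # deterministic sign: largest-magnitude entry of each column positive
    for c in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, c]))
        if V[j, c] < 0:
            V[:, c] = -V[:, c]
    return V, evals


def lle(X: np.ndarray, k: int = 12, d: int = 2) -> EmbeddingResult:
    """Full LLE: neighbors -> weights -> coordinates."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < d + 1:
        raise ValidationError(f"need k >= d+1 (k={k}, d={d})")
    neighbors = knn_neighbors(X, k)
    W, eps = reconstruction_weights(X, neighbors)
    V, evals = embed_coordinates(W, d)
    psi = float(np.sum(evals) * n)  # Psi(V) = trace(V^T M V) = n * sum(lambda)
    return EmbeddingResult(V=V, k=k, W=W, neighbors=neighbors,
                           reconstruction_error=eps, embedding_cost=psi,
                           eigenvalues=evals)
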