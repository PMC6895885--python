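"""Core-periphery structure of the embedded connection cloud.

The embedding V is turned into an unweighted kNN graph (union
symmetrization: edge (i, j) if either point is among the other's k nearest
neighbors). A nonlinear spectral method (NSM) then assigns every node a
positive core score by power iteration on the fixed-point map of the
alpha-norm core-periphery objective

    f_alpha(x) = sum_ij A_ij * (x_i^alpha + x_j^alpha)^(1/alpha),

whose (sub)gradient map is

    M(x)_i = sum_j A_ij * (x_i^alpha + x_j^alpha)^((1-alpha)/alpha) * x_i^(alpha-1).

Iterating x <- M(x)/||M(x)|| from a uniform positive start ascends
f_alpha; at convergence the max-normalized score c = x / max(x) in (0, 1]
is the coreness of each connection. Large alpha approximates the max-norm
objective, which rewards edges touching at least one high-score node —
the defining trait of a core.

Quality of a candidate ranking is read off the core-periphery profile
gamma: with nodes sorted by ascending score, gamma_k is the ratio of
edges internal to the k lowest-scored nodes to all edges touching them. A
strong core-periphery structure keeps gamma near zero until k approaches
n - |core|.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.sparse as sp

from .core_io import NumericError, PairIndex, ValidationError
from .lle import knn_neighbors

__all__ = ["AdjacencyGraph", "CorenessVector", "knn_adjacency", "nsm_coreness",
           "gamma_profile", "coreness_to_matrix"]


@dataclasses.dataclass
class AdjacencyGraph:
    """Symmetric unweighted graph over the embedded connections."""

    A: sp.csr_matrix
    k_graph: int
    symmetrization: str = "union"

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.A)
        if (A != A.T).nnz:
            raise ValidationError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValidationError("adjacency must have zero diagonal")
        self.A = A

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return self.A.nnz // 2


@dataclasses.dataclass
class CorenessVector:
    """Max-normalized NSM core scores, one per connection."""

    c: np.ndarray
    iterations: int
    final_rel_change: float
    alpha: float
    objective_trace: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.c <= 0):
            raise NumericError("coreness values must be strictly positive")


def knn_adjacency(V: np.ndarray, k_graph: int) -> AdjacencyGraph:
    """Union-symmetrized kNN graph of the embedding (Euclidean metric)."""
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    if k_graph >= n:
        raise ValidationError(f"k_graph={k_graph} must be smaller than n={n}")
    nbrs = knn_neighbors(V, k_graph)
    rows = np.repeat(np.arange(n), k_graph)
    A = sp.csr_matrix((np.ones(n * k_graph), (rows, nbrs.ravel())), shape=(n, n))
    A = A.maximum(A.T)          # union symmetrization
    A.data[:] = 1.0
    A.setdiag(0)
    A.eliminate_zeros()
    return AdjacencyGraph(A=A, k_graph=k_graph)


def _nsm_objective(x: np.ndarray, A: sp.csr_matrix, alpha: float) -> float:
    i, j = A.nonzero()
    return float(np.power(x[i] ** alpha + x[j] ** alpha, 1.0 / alpha).sum())


def _nsm_iterate(A: sp.csr_matrix, alpha: float, tol: float,
                 max_iter: int) -> tuple[np.ndarray, int, float, np.ndarray]:
    n = A.shape[0]
    x = np.ones(n) / np.sqrt(n)
    coo = A.tocoo()
    i, j = coo.row, coo.col
    trace = []
    rel = np.inf
    for it in range(1, max_iter + 1):
        trace.append(_nsm_objective(x, A, alpha))
        # M(x)_i = sum_j A_ij (x_i^a + x_j^a)^((1-a)/a) x_i^(a-1);
        # 0-homogeneous, so x is max-normalized first for stability
        u = x / x.max()
        pa = u ** alpha
        w = np.power(pa[i] + pa[j], (1.0 - alpha) / alpha)
        m = np.bincount(i, weights=w, minlength=n) * u ** (alpha - 1.0)
        if not np.all(np.isfinite(m)) or m.max() <= 0:
            raise NumericError("NSM iteration produced non-positive or non-finite scores")
        # isolated nodes have no edges; keep them at the floor of the scale
        m[m == 0] = m[m > 0].min() * 1e-12 if (m > 0).any() else 1.0
        x_new = m / np.linalg.norm(m)
        rel = np.linalg.norm(x - x_new) / np.linalg.norm(x_new)
        x = x_new
        if rel < tol:
            break
    else:
        warnings.warn(
            f"NSM did not reach tolerance {tol} in {max_iter} iterations "
            f"(last relative change {rel:.3g}); returning last iterate",
            RuntimeWarning, stacklevel=3,
        )
    trace.append(_nsm_objective(x, A, alpha))
    return x, it, float(rel), np.asarray(trace)


def nsm_coreness(graph: AdjacencyGraph, alpha: float = 10.0, tol: float = 1e-6,
                 max_iter: int = 1000) -> CorenessVector:
    """Nonlinear spectral core score for every node, max-normalized to (0, 1].

    Disconnected graphs are handled per connected component (with a
    warning); the final vector is normalized globally by its maximum.
    """
    if alpha <= 1:
        raise ValidationError(f"alpha must exceed 1, got {alpha}")
    A = graph.A
    if A.nnz == 0:
        raise ValidationError("empty graph: coreness undefined")
    n_comp, comp = sp.csgraph.connected_components(A, directed=False)
    x = np.empty(graph.n)
    iters, rel = 0, 0.0
    traces = []
    if n_comp > 1:
        warnings.warn(
            f"kNN graph has {n_comp} connected components; running NSM per "
            "component and normalizing coreness globally",
            RuntimeWarning, stacklevel=2,
        )
    for cid in range(n_comp):
        idx = np.flatnonzero(comp == cid)
        if idx.size == 1:
            x[idx] = 1e-12  # isolated node: minimal coreness
            continue
        sub = A[np.ix_(idx, idx)].tocsr()
        xs, its, r, tr = _nsm_iterate(sub, alpha, tol, max_iter)
        x[idx] = xs
        iters = max(iters, its)
        rel = max(rel, r)
        traces.append(tr)
    c = x / x.max()
    c = np.maximum(c, 1e-15)  # strictly positive by contract
    objective = traces[0] if len(traces) == 1 else np.concatenate(traces)
    return CorenessVector(c=c, iterations=iters, final_rel_change=rel,
                          alpha=alpha, objective_trace=objective)


def gamma_profile(x: np.ndarray, graph: AdjacencyGraph) -> np.ndarray:
    """Core-periphery profile gamma_k for k = 1..n.

    Nodes are sorted by ascending score (ties broken by index). gamma_k is
    the number of (ordered) adjacency entries internal to the k
    lowest-scored nodes divided by the total adjacency entries touching
    them; 0 when the denominator is 0. With at least one edge, gamma_n = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != graph.n:
        raise ValidationError(f"score length {x.shape[0]} != graph size {graph.n}")
    order = np.argsort(x, kind="stable")
    rank = np.empty(graph.n, dtype=np.intp)
    rank[order] = np.arange(graph.n)
    A = graph.A.tocoo()
    deg = np.asarray(graph.A.sum(axis=1)).ravel()
    # numerator: ordered pairs (i, j) both inside the first k of the ranking;
    # an edge with max rank m joins the numerator at k = m + 1
    edge_max_rank = np.maximum(rank[A.row], rank[A.col])
    num = np.cumsum(np.bincount(edge_max_rank, minlength=graph.n).astype(float))
    den = np.cumsum(deg[order])
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(den > 0, num / den, 0.0)
    return gamma


def coreness_to_matrix(c: np.ndarray, pair_index: PairIndex) -> np.ndarray:
    """Rearrange the coreness vector into the symmetric R x R core-quality matrix."""
    c = np.asarray(c, dtype=float)
    if c.shape != (pair_index.n,):
        raise ValidationError(f"coreness length {c.shape} != {pair_index.n} pairs")
    return pair_index.vector_to_matrix(c, diagonal=np.nan)
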