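import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from dfcmanifold import (
    AdjacencyGraph,
    PairIndex,
    ValidationError,
    coreness_to_matrix,
    gamma_profile,
    gen_core_periphery_graph,
    knn_adjacency,
    nsm_coreness,
)


def graph_from_dense(A):
    return AdjacencyGraph(A=sp.csr_matrix(np.asarray(A, dtype=float)), k_graph=0)


class TestKnnAdjacency:
    def test_saturation(self, rng):
        V = rng.standard_normal((12, 3))
        g = knn_adjacency(V, 11)
        assert g.n_edges == 12 * 11 // 2  # complete graph

    def test_square_geometry(self):
        # rectangle: each vertex's nearest neighbor is across the short edge
        V = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 3.0], [1.0, 3.0]])
        g = knn_adjacency(V, 1)
        A = g.A.toarray()
        assert A[0, 1] == 1 and A[2, 3] == 1
        assert A[0, 2] == 0 and A[1, 3] == 0
        assert np.array_equal(A, A.T)

    def test_rigid_motion_invariance(self, rng):
        V = rng.standard_normal((80, 4))
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        g1 = knn_adjacency(V, 6)
        g2 = knn_adjacency(V @ Q + 3.7, 6)
        assert (g1.A != g2.A).nnz == 0

    def test_union_symmetrization(self):
        # asymmetric nearest-neighbor relation still yields an edge
        V = np.array([[0.0], [1.0], [1.6]])
        g = knn_adjacency(V, 1)
        A = g.A.toarray()
        assert A[0, 1] == 1  # 1's nearest is 1.6, but 0's nearest is 1


class TestNsm:
    def test_complete_graph_symmetry(self):
        g = graph_from_dense(np.ones((6, 6)) - np.eye(6))
        cv = nsm_coreness(g)
        assert np.allclose(cv.c, 1.0)

    def test_star_center_is_core(self):
        A = np.zeros((6, 6))
        A[0, 1:] = A[1:, 0] = 1
        cv = nsm_coreness(graph_from_dense(A))
        assert cv.c[0] == 1.0
        assert np.all(cv.c[1:] < 1.0)
        assert np.allclose(cv.c[1:], cv.c[1], rtol=1e-6)  # leaves equal

    def test_star_matches_brute_force_objective(self):
        # the symmetric score family (center a, leaves b), 5b^2 + a^2 = 1:
        # grid-maximize f_alpha; the optimum puts everything on the center
        # (b -> 0), and the NSM fixed point lands at the same corner
        alpha = 10.0
        a_grid = np.linspace(1e-3, 1.0, 20001)
        b_grid = np.sqrt(np.clip(1 - a_grid**2, 0, None) / 5)
        f = 2 * 5 * (a_grid**alpha + b_grid**alpha) ** (1 / alpha)
        a_best, b_best = a_grid[np.argmax(f)], b_grid[np.argmax(f)]
        assert a_best > b_best          # brute force: center is core
        assert b_best / a_best < 1e-3   # ...and the leaf score collapses
        A = np.zeros((6, 6))
        A[0, 1:] = A[1:, 0] = 1
        cv = nsm_coreness(graph_from_dense(A), alpha=alpha, tol=1e-10)
        assert cv.c[0] == 1.0
        assert np.all(cv.c[1:] < 1e-3)  # matches the brute-force corner

    def test_objective_monotone(self):
        A, _ = gen_core_periphery_graph(80, 0.25, 0.9, 0.4, 0.05, seed=3)
        cv = nsm_coreness(graph_from_dense(A))
        assert np.all(np.diff(cv.objective_trace) >= -1e-8)

    def test_planted_core_recovery_beats_degree(self):
        nsm_aucs, deg_aucs = [], []
        for seed in range(10):
            A, is_core = gen_core_periphery_graph(100, 0.2, 0.9, 0.5, 0.05, seed=seed)
            g = graph_from_dense(A)
            cv = nsm_coreness(g)
            nsm_aucs.append(roc_auc_score(is_core, cv.c))
            deg_aucs.append(roc_auc_score(is_core, np.asarray(g.A.sum(axis=1)).ravel()))
        assert np.min(nsm_aucs) >= 0.95
        assert np.mean(nsm_aucs) >= np.mean(deg_aucs) - 1e-12

    def test_relabeling_equivariance(self, rng):
        A, _ = gen_core_periphery_graph(60, 0.25, 0.9, 0.4, 0.05, seed=9)
        perm = rng.permutation(60)
        c1 = nsm_coreness(graph_from_dense(A)).c
        c2 = nsm_coreness(graph_from_dense(A[np.ix_(perm, perm)])).c
        assert np.allclose(c2, c1[perm], rtol=1e-6)

    def test_disconnected_graph_warns(self):
        A = np.zeros((6, 6))
        A[0, 1] = A[1, 0] = 1
        A[2, 3] = A[3, 2] = A[3, 4] = A[4, 3] = A[2, 4] = A[4, 2] = 1
        A[5, 2] = A[2, 5] = 1
        with pytest.warns(RuntimeWarning, match="components"):
            cv = nsm_coreness(graph_from_dense(A))
        assert cv.c.max() == 1.0 and np.all(cv.c > 0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            nsm_coreness(graph_from_dense(np.zeros((4, 4))))


class TestGammaProfile:
    def test_k3_closed_form(self):
        g = graph_from_dense(np.ones((3, 3)) - np.eye(3))
        gamma = gamma_profile(np.array([1.0, 2.0, 3.0]), g)
        assert gamma[0] == 0.0
        assert gamma[1] == 0.5   # 2 ordered internal pairs / 4 endpoints
        assert gamma[2] == 1.0

    def test_ideal_core_periphery_is_zero_on_periphery(self):
        A, is_core = gen_core_periphery_graph(40, 0.25, 1.0, 1.0, 0.0, seed=0)
        g = graph_from_dense(A)
        score = is_core.astype(float)  # periphery scored below core
        gamma = gamma_profile(score, g)
        n_periph = int((~is_core).sum())
        assert np.all(gamma[:n_periph] == 0.0)
        assert gamma[-1] == 1.0

    def test_monotone_transform_invariance(self, rng):
        A, _ = gen_core_periphery_graph(50, 0.3, 0.8, 0.4, 0.1, seed=4)
        g = graph_from_dense(A)
        x = rng.uniform(0.1, 1.0, 50)
        assert np.array_equal(gamma_profile(x, g), gamma_profile(np.exp(5 * x), g))

    def test_length_mismatch(self):
        g = graph_from_dense(np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValidationError):
            gamma_profile(np.ones(4), g)


class TestCorenessMatrix:
    def test_constant_and_round_trip(self, rng):
        pidx = PairIndex(9)
        C = coreness_to_matrix(np.full(pidx.n, 0.4), pidx)
        off = ~np.eye(9, dtype=bool)
        assert np.all(C[off] == 0.4)
        c = rng.uniform(0.1, 1.0, pidx.n)
        assert np.array_equal(pidx.matrix_to_vector(coreness_to_matrix(c, pidx)), c)

    def test_single_hot_pair(self):
        pidx = PairIndex(6)
        c = np.full(pidx.n, 0.5)
        c[pidx.to_index(1, 4)] = 1.0
        C = coreness_to_matrix(c, pidx)
        hot = np.argwhere(C == 1.0)
        assert {tuple(x) for x in hot} == {(1, 4), (4, 1)}
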