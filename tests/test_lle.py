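import numpy as np
import pytest
import scipy.sparse as sp

from dfcmanifold import (
    ValidationError,
    knn_neighbors,
    lle,
    reconstruction_weights,
)
from dfcmanifold.lle import embed_coordinates


def assert_lle_constraints(emb):
    n, d = emb.V.shape
    row_sums = np.asarray(emb.W.sum(axis=1)).ravel()
    assert np.allclose(row_sums, 1.0, atol=1e-10)
    scale = np.abs(emb.V).max()
    assert np.abs(emb.V.sum(axis=0)).max() < 1e-8 * scale * n
    cov = emb.V.T @ emb.V
    assert np.allclose(cov, n * np.eye(d), rtol=1e-6, atol=1e-6 * n)


class TestKnn:
    def test_tie_breaks_to_lower_index(self):
        X = np.array([[0.0], [1.0], [2.0]])
        nb = knn_neighbors(X, 1)
        assert nb[1, 0] == 0  # both endpoints at distance 1; lower index wins

    def test_matches_brute_force(self, rng):
        X = rng.standard_normal((200, 6))
        nb = knn_neighbors(X, 7)
        D = np.linalg.norm(X[:, None] - X[None], axis=2)
        np.fill_diagonal(D, np.inf)
        for i in range(200):
            expected = np.argsort(D[i], kind="stable")[:7]
            assert np.array_equal(nb[i], expected)

    def test_duplicate_is_first_neighbor(self, rng):
        X = rng.standard_normal((50, 3))
        X[13] = X[4]
        nb = knn_neighbors(X, 3)
        assert nb[13, 0] == 4 and nb[4, 0] == 13

    def test_k_too_large(self, rng):
        with pytest.raises(ValidationError):
            knn_neighbors(rng.standard_normal((5, 2)), 5)


class TestWeights:
    def test_exact_duplicate_gets_full_weight(self, rng):
        X = rng.standard_normal((30, 4))
        X[7] = X[2]
        nb = knn_neighbors(X, 5)
        W, _ = reconstruction_weights(X, nb)
        W = W.toarray()
        assert abs(W[7, 2] - 1.0) < 1e-6
        assert np.abs(np.delete(W[7], 2)).max() < 1e-6

    def test_symmetric_midpoint(self):
        # point at the centroid of two symmetric neighbors -> (1/2, 1/2)
        X = np.array([[0.0, 0.0], [1.0, 0.3], [-1.0, -0.3], [5.0, 5.0]])
        nb = np.array([[1, 2], [0, 2], [0, 1], [0, 1]])
        W, eps = reconstruction_weights(X, nb)
        assert np.allclose(W.toarray()[0, [1, 2]], [0.5, 0.5], atol=1e-9)

    def test_rigid_motion_invariance(self, rng):
        X = rng.standard_normal((150, 5))
        nb = knn_neighbors(X, 8)
        W0 = reconstruction_weights(X, nb)[0].toarray()
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        X2 = X @ Q + rng.standard_normal(5)  # rotation + translation
        W1 = reconstruction_weights(X2, nb)[0].toarray()
        assert np.abs(W0 - W1).max() < 1e-8

    def test_reconstruction_error_non_increasing_in_k(self, planar_cloud):
        errs = []
        for k in (4, 6, 8):
            nb = knn_neighbors(planar_cloud, k)
            errs.append(reconstruction_weights(planar_cloud, nb)[1])
        assert errs[0] >= errs[1] - 1e-12 and errs[1] >= errs[2] - 1e-12


class TestEmbedding:
    def test_planar_cloud_constraints_and_cost(self, planar_cloud):
        emb = lle(planar_cloud, k=8, d=2)
        assert_lle_constraints(emb)
        assert abs(emb.embedding_cost) < 1e-8
        # local rank order preserved: embedded neighbors overlap original ones
        nb_hi = knn_neighbors(planar_cloud, 8)
        nb_lo = knn_neighbors(emb.V, 8)
        overlap = np.mean([len(set(a) & set(b)) / 8 for a, b in zip(nb_hi, nb_lo)])
        assert overlap > 0.9

    def test_generic_cloud_constraints(self, rng):
        X = rng.standard_normal((200, 5))
        emb = lle(X, k=10, d=3)
        assert_lle_constraints(emb)

    def test_dense_oracle_subspace(self, rng):
        # V spans the same subspace as an independent dense eigendecomposition
        X = rng.standard_normal((150, 12))
        emb = lle(X, k=9, d=3)
        IW = np.eye(150) - emb.W.toarray()
        M = IW.T @ IW
        evals, evecs = np.linalg.eigh(M)
        oracle = evecs[:, 1:4]  # drop constant mode
        # principal angles between the two 3-dim subspaces
        s = np.linalg.svd(oracle.T @ (emb.V / np.sqrt(150)), compute_uv=False)
        assert np.all(1 - s < 1e-6)

    def test_curved_sheet_neighborhood_preservation(self, curved_sheet):
        emb = lle(curved_sheet, k=12, d=2)
        assert_lle_constraints(emb)
        nb_hi = knn_neighbors(curved_sheet, 12)
        nb_lo = knn_neighbors(emb.V, 12)
        overlap = np.mean([len(set(a) & set(b)) / 12 for a, b in zip(nb_hi, nb_lo)])
        assert overlap > 0.7

    def test_cross_check_against_sklearn(self, curved_sheet):
        # independent implementation agrees on the embedded geometry
        from sklearn.manifold import LocallyLinearEmbedding
        emb = lle(curved_sheet, k=12, d=2)
        sk = LocallyLinearEmbedding(n_neighbors=12, n_components=2,
                                    random_state=0).fit_transform(curved_sheet)
        r0 = abs(np.corrcoef(emb.V[:, 0], sk[:, 0])[0, 1])
        r1 = abs(np.corrcoef(emb.V[:, 1], sk[:, 1])[0, 1])
        assert min(r0, r1) > 0.85

    def test_deterministic(self, planted_dfc):
        S, _, _ = planted_dfc
        e1 = lle(S, k=12, d=6)
        e2 = lle(S, k=12, d=6)
        assert np.array_equal(e1.V, e2.V)

    def test_sign_convention(self, rng):
        X = rng.standard_normal((120, 8))
        emb = lle(X, k=10, d=4)
        for c in range(4):
            j = np.argmax(np.abs(emb.V[:, c]))
            assert emb.V[j, c] > 0

    def test_module_arms_are_angularly_coherent(self, planted_dfc):
        S, membership, _ = planted_dfc
        emb = lle(S, k=12, d=6)
        U = emb.V / np.linalg.norm(emb.V, axis=1, keepdims=True)
        cos = U @ U.T
        same = membership[:, None] == membership[None, :]
        off_diag = ~np.eye(len(membership), dtype=bool)
        within = cos[same & off_diag].mean()
        across = cos[~same].mean()
        assert within > across

    def test_bad_dimensions(self, rng):
        X = rng.standard_normal((30, 4))
        with pytest.raises(ValidationError):
            lle(X, k=3, d=5)  # k < d + 1
        with pytest.raises(ValidationError):
            embed_coordinates(sp.identity(10, format="csr"), d=10)
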