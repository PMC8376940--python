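"""OLPP: PCA pre-projection, neighbourhood graph, heat weights, graph
Laplacian, orthogonal basis extraction (checked against independent
eigensolver and brute-force oracles), and the fitted transform."""

import numpy as np
import pytest
import scipy.linalg

from ppiforest.olpp import (
    OLPPConfig,
    build_knn_graph,
    degree_laplacian,
    fit_olpp,
    heat_weights,
    load_olpp_model,
    orthogonal_basis,
    pca_projection,
    save_olpp_model,
    transform,
)


def _graph_matrices(x, n_neighbors=4, heat_t="auto"):
    adj = build_knn_graph(x, n_neighbors)
    w = heat_weights(x, adj, heat_t)
    return degree_laplacian(w)


class TestPcaProjection:
    def test_planar_data_keeps_two_components(self, rng):
        coords = rng.normal(size=(40, 2))
        basis = rng.normal(size=(2, 5))
        x = coords @ basis  # exactly rank 2 in 5-D
        _, w = pca_projection(x, pca_tol=1e-9)
        assert w.shape == (5, 2)

    def test_full_rank_isotropic_keeps_all(self, rng):
        x = rng.normal(size=(50, 4))
        _, w = pca_projection(x)
        assert w.shape[1] == 4

    def test_constant_data_is_degenerate(self):
        x = np.ones((5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            pca_projection(x)

    def test_columns_are_unit_orthonormal(self, rng):
        x = rng.normal(size=(30, 6))
        _, w = pca_projection(x)
        np.testing.assert_allclose(w.T @ w, np.eye(w.shape[1]), atol=1e-10)


class TestKnnGraph:
    def test_max_neighbors_gives_complete_graph(self, rng):
        x = rng.normal(size=(8, 3))
        adj = build_knn_graph(x, 7)
        expected = ~np.eye(8, dtype=bool)
        np.testing.assert_array_equal(adj, expected)

    def test_1d_line_or_symmetrization(self):
        x = np.array([[0.0], [1.0], [10.0]])
        adj = build_knn_graph(x, 1)
        # 0 and 1 pick each other; 10 picks 1; OR-symmetrized
        expected = np.array(
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool
        )
        np.testing.assert_array_equal(adj, expected)

    def test_symmetric_no_self_edges(self, rng):
        x = rng.normal(size=(20, 4))
        adj = build_knn_graph(x, 3)
        np.testing.assert_array_equal(adj, adj.T)
        assert not adj.diagonal().any()

    def test_neighbor_count_validation(self, rng):
        x = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            build_knn_graph(x, 5)


class TestHeatWeights:
    def test_coincident_linked_points_weight_one(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        w = heat_weights(x, adj, heat_t=2.0)
        assert w[0, 1] == pytest.approx(1.0)

    def test_distance_equal_t_gives_inverse_e(self):
        x = np.array([[0.0], [2.0]])
        adj = np.array([[0, 1], [1, 0]], dtype=bool)
        w = heat_weights(x, adj, heat_t=4.0)  # ||x0-x1||^2 = 4 = t
        assert w[0, 1] == pytest.approx(np.exp(-1.0))

    def test_unlinked_pairs_are_zero(self, rng):
        x = rng.normal(size=(6, 2))
        adj = build_knn_graph(x, 1)
        w = heat_weights(x, adj, "auto")
        assert (w[~adj] == 0).all()

    def test_auto_t_is_mean_squared_edge_distance(self):
        x = np.array([[0.0], [1.0], [3.0]])
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        w = heat_weights(x, adj, "auto")  # edge sq-dists 1 and 4 -> t = 2.5
        assert w[0, 1] == pytest.approx(np.exp(-1 / 2.5))
        assert w[1, 2] == pytest.approx(np.exp(-4 / 2.5))

    def test_auto_requires_edges(self):
        x = np.zeros((3, 1))
        with pytest.raises(ValueError, match="edge"):
            heat_weights(x, np.zeros((3, 3), dtype=bool), "auto")


class TestDegreeLaplacian:
    def test_two_node_example(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        d, l = degree_laplacian(w)
        np.testing.assert_array_equal(d, np.eye(2))
        np.testing.assert_array_equal(l, [[1, -1], [-1, 1]])

    def test_zero_weights(self):
        d, l = degree_laplacian(np.zeros((3, 3)))
        assert (d == 0).all() and (l == 0).all()

    def test_row_sums_zero_and_psd(self, rng):
        a = rng.uniform(0, 1, size=(10, 10))
        w = (a + a.T) / 2
        np.fill_diagonal(w, 0)
        _, l = degree_laplacian(w)
        np.testing.assert_allclose(l.sum(axis=1), 0, atol=1e-10)
        assert np.linalg.eigvalsh(l).min() >= -1e-8

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            degree_laplacian(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestOrthogonalBasis:
    def test_d1_matches_generalized_eigensolver(self, rng):
        """First direction equals the smallest generalized eigenvector of
        the locality objective, up to sign, on random problems."""
        for _ in range(20):
            x = rng.normal(size=(30, 5))
            mean, wp = pca_projection(x)
            z = (x - mean) @ wp
            d, l = _graph_matrices(z)
            xp = z.T
            o1 = orthogonal_basis(xp, d, l, 1, ridge=0.0)[:, 0]
            xdx, xlx = xp @ d @ xp.T, xp @ l @ xp.T
            _, evecs = scipy.linalg.eigh(xlx, xdx)
            v = evecs[:, 0] / np.linalg.norm(evecs[:, 0])
            assert abs(v @ o1) >= 1 - 1e-8

    def test_pairwise_orthogonality_d4(self, rng):
        x = rng.normal(size=(30, 5))
        mean, wp = pca_projection(x)
        z = (x - mean) @ wp
        d, l = _graph_matrices(z)
        basis = orthogonal_basis(z.T, d, l, 4)
        g = basis.T @ basis
        assert np.abs(g - np.eye(4)).max() <= 1e-8

    def test_d2_matches_brute_force_constrained_minimizer(self, rng):
        """Second direction equals the brute-force minimizer of the
        locality quotient over a fine angular grid of the plane orthogonal
        to the first direction (3-feature problem)."""
        x = rng.normal(size=(25, 3))
        z = x - x.mean(axis=0)
        d, l = _graph_matrices(z, n_neighbors=3)
        xp = z.T
        basis = orthogonal_basis(xp, d, l, 2, ridge=0.0)
        o1, o2 = basis[:, 0], basis[:, 1]
        xdx, xlx = xp @ d @ xp.T, xp @ l @ xp.T
        # orthonormal basis of the complement of o1
        q, _ = np.linalg.qr(np.column_stack([o1, np.eye(3)[:, :2]]))
        q1, q2 = q[:, 1], q[:, 2]
        thetas = np.linspace(0, np.pi, 200001)
        ws = np.outer(np.cos(thetas), q1) + np.outer(np.sin(thetas), q2)
        quot = np.einsum("ij,jk,ik->i", ws, xlx, ws) / np.einsum(
            "ij,jk,ik->i", ws, xdx, ws
        )
        w_best = ws[np.argmin(quot)]
        assert abs(w_best @ o2) >= 1 - 1e-6

    def test_embed_dim_exceeding_rank_rejected(self, rng):
        x = rng.normal(size=(10, 3))
        z = x - x.mean(axis=0)
        d, l = _graph_matrices(z, n_neighbors=3)
        with pytest.raises(ValueError, match="embed_dim"):
            orthogonal_basis(z.T, d, l, 4)


class TestFitTransform:
    def test_fit_is_deterministic(self, rng):
        x = rng.normal(size=(40, 8))
        cfg = OLPPConfig(n_neighbors=4, embed_dim=3)
        m1, m2 = fit_olpp(x, cfg), fit_olpp(x, cfg)
        np.testing.assert_array_equal(m1.w_combined, m2.w_combined)
        np.testing.assert_array_equal(m1.mean, m2.mean)

    def test_locality_preserved_for_two_clusters(self, rng):
        centers = np.zeros((2, 10))
        centers[1, :] = 8.0
        x = np.vstack(
            [rng.normal(c, 1.0, size=(30, 10)) for c in centers]
        )
        labels = np.repeat([0, 1], 30)
        model = fit_olpp(x, OLPPConfig(n_neighbors=5, embed_dim=2))
        y = transform(model, x)

        def ratio(data):
            from scipy.spatial.distance import pdist, squareform

            d = squareform(pdist(data))
            same = labels[:, None] == labels[None, :]
            np.fill_diagonal(same, False)
            within = d[same].mean()
            between = d[~same & ~np.eye(60, dtype=bool)].mean()
            return within / between

        assert ratio(y) < ratio(x)

    def test_full_dim_embedding_has_full_column_rank(self, rng):
        x = rng.normal(size=(25, 4))
        model = fit_olpp(x, OLPPConfig(n_neighbors=3, embed_dim=4))
        assert np.linalg.matrix_rank(model.w_combined) == 4

    def test_transform_of_training_mean_is_zero(self, rng):
        x = rng.normal(size=(20, 5))
        model = fit_olpp(x, OLPPConfig(n_neighbors=3, embed_dim=2))
        np.testing.assert_allclose(
            transform(model, model.mean[None, :]), 0, atol=1e-12
        )

    def test_transform_is_linear_and_rowwise(self, rng):
        x = rng.normal(size=(20, 5))
        model = fit_olpp(x, OLPPConfig(n_neighbors=3, embed_dim=2))
        x1, x2 = rng.normal(size=(2, 5))
        a = 0.3
        combo = a * x1 + (1 - a) * x2
        y = transform(model, np.vstack([x1, x2, combo]))
        np.testing.assert_allclose(a * y[0] + (1 - a) * y[1], y[2], atol=1e-10)
        np.testing.assert_allclose(transform(model, x1[None, :])[0], y[0])

    def test_dimension_mismatch_rejected(self, rng):
        x = rng.normal(size=(20, 5))
        model = fit_olpp(x, OLPPConfig(n_neighbors=3, embed_dim=2))
        with pytest.raises(ValueError, match="features"):
            transform(model, np.zeros((1, 7)))

    def test_embed_dim_clamped_to_rank_with_warning(self, rng):
        coords = rng.normal(size=(30, 2))
        x = coords @ rng.normal(size=(2, 6))  # rank 2
        with pytest.warns(UserWarning, match="clamping"):
            model = fit_olpp(x, OLPPConfig(n_neighbors=3, embed_dim=5))
        assert model.embed_dim == 2

    def test_json_round_trip(self, rng, tmp_path):
        x = rng.normal(size=(20, 5))
        model = fit_olpp(x, OLPPConfig(n_neighbors=3, embed_dim=2))
        path = tmp_path / "model.json"
        save_olpp_model(model, path)
        back = load_olpp_model(path)
        np.testing.assert_array_equal(back.w_combined, model.w_combined)
        probe = rng.normal(size=(4, 5))
        np.testing.assert_array_equal(transform(back, probe), transform(model, probe))


def test_graph_weight_invariants_on_random_data(rng):
    """Affinity and Laplacian invariants over many random datasets."""
    for _ in range(15):
        n = int(rng.integers(10, 25))
        x = rng.normal(size=(n, int(rng.integers(2, 6))))
        adj = build_knn_graph(x, int(rng.integers(1, min(6, n - 1) + 1)))
        w = heat_weights(x, adj, "auto")
        assert np.array_equal(w, w.T)
        assert (np.diag(w) == 0).all()
        assert (w >= 0).all() and (w <= 1).all()
        _, l = degree_laplacian(w)
        np.testing.assert_allclose(l.sum(axis=1), 0, atol=1e-10)
        assert np.linalg.eigvalsh(l).min() >= -1e-8
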