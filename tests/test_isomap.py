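"""Isomap graph construction, geodesics, embedding, out-of-sample projection."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

import chemography as cg
from chemography.data import ConfigurationError
from chemography.isomap import (
    build_graph,
    embed,
    fit_isomap,
    fit_s_isomap,
    geodesic_distances,
    out_of_sample,
    supervised_dissimilarity,
)


class TestSupervisedDissimilarity:
    def test_closed_form_values(self):
        # d=0 same class -> 0; d=0 cross with alpha=0.3 -> 0.7; d^2=beta cross -> e - 0.3
        assert supervised_dissimilarity(0.0, True, 0.3, 1.0) == pytest.approx(0.0)
        assert supervised_dissimilarity(0.0, False, 0.3, 1.0) == pytest.approx(0.7)
        assert supervised_dissimilarity(1.0, False, 0.3, 1.0) == pytest.approx(np.e - 0.3)

    def test_alpha_zero_separates_branch_ranges(self, rng):
        """alpha=0: every same-class value < 1 <= every cross-class value."""
        d = rng.random(500) * 10
        same = supervised_dissimilarity(d, np.ones(500, bool), 0.0, 3.0)
        cross = supervised_dissimilarity(d, np.zeros(500, bool), 0.0, 3.0)
        assert same.max() < 1.0 <= cross.min()

    def test_same_class_branch_monotone_in_distance(self):
        d = np.linspace(0, 5, 50)
        vals = supervised_dissimilarity(d, np.ones(50, bool), 0.3, 2.0)
        assert np.all(np.diff(vals) > 0)


class TestGraph:
    def test_collinear_chain_with_k1_connects_fully(self):
        X = np.arange(4, dtype=float)[:, None]
        adj, mask, _, _ = build_graph(X, None, k=1)
        assert mask.all()
        # chain: 0-1, 1-2 or 2-3 pattern, connected
        assert (adj > 0).sum() >= 6  # symmetric storage of >= 3 edges

    def test_two_far_blobs_drop_smaller_component(self, rng):
        X = np.vstack([rng.standard_normal((12, 3)), rng.standard_normal((5, 3)) + 100])
        with pytest.warns(UserWarning, match="dropped"):
            m = fit_isomap(X, k=3)
        assert m.component_mask.sum() == 12
        assert len(m.dropped_ids) == 5

    def test_supervised_alpha_zero_cross_edges_heavier(self, rng):
        X = rng.standard_normal((30, 4))
        y = (rng.random(30) > 0.5).astype(int)
        same = y[:, None] == y[None, :]
        D = supervised_dissimilarity(squareform(pdist(X)), same, 0.0, 5.0)
        iu = np.triu_indices(30, 1)
        assert D[iu][same[iu]].max() < 1.0 <= D[iu][~same[iu]].min()

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ConfigurationError, match="k="):
            build_graph(rng.standard_normal((5, 2)), None, k=5)


class TestGeodesics:
    def test_chain_distance_is_path_sum(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        D = geodesic_distances(adj)
        assert D[0, 2] == pytest.approx(2.0)

    def test_complete_euclidean_graph_keeps_direct_edges(self, rng):
        X = rng.standard_normal((10, 3))
        adj, _, _, _ = build_graph(X, None, k=9)
        D = geodesic_distances(adj)
        np.testing.assert_allclose(D, squareform(pdist(X)), atol=1e-12)

    def test_matches_floyd_warshall_oracle(self, rng):
        """Dijkstra all-pairs against an independent Floyd-Warshall loop."""
        n = 20
        X = rng.standard_normal((n, 3))
        adj, mask, _, _ = build_graph(X, None, k=4)
        n = mask.sum()
        D = geodesic_distances(adj)
        ref = np.where(adj > 0, adj, np.inf)
        np.fill_diagonal(ref, 0.0)
        for m in range(n):
            for i in range(n):
                for j in range(n):
                    ref[i, j] = min(ref[i, j], ref[i, m] + ref[m, j])
        np.testing.assert_allclose(D, ref, atol=1e-12)

    def test_geodesic_never_undercuts_an_edge(self, rng):
        X = rng.standard_normal((25, 3))
        adj, _, _, _ = build_graph(X, None, k=4)
        D = geodesic_distances(adj)
        edges = adj > 0
        assert np.all(D[edges] <= adj[edges] + 1e-12)

    def test_disconnected_input_rejected(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 1.0
        with pytest.raises(ConfigurationError, match="disconnected"):
            geodesic_distances(adj)


class TestEmbedding:
    def test_flat_plane_reproduces_distances(self, rng):
        """2-D plane in 10-D with a complete graph: exact distance recovery."""
        P = rng.random((40, 2)) * 10
        B = np.linalg.qr(rng.standard_normal((10, 10)))[0][:, :2]
        m = fit_isomap(P @ B.T, k=39)
        assert np.abs(pdist(P @ B.T) - pdist(m.embedding)).max() < 1e-6

    def test_equilateral_triangle_recovered(self):
        side = 2.5
        X = np.array([[0, 0], [side, 0], [side / 2, side * np.sqrt(3) / 2]])
        D = squareform(pdist(X))
        coords, evals, _ = embed(D, d=2)
        np.testing.assert_allclose(pdist(coords), [side] * 3, atol=1e-8)

    def test_swiss_roll_rank_correlation(self, swiss_roll):
        data, _ = swiss_roll
        m = fit_isomap(data.X, k=8)
        rho = spearmanr(pdist(m.embedding),
                        squareform(m.D_geo, checks=False)).statistic
        assert rho > 0.99

    def test_chain_embedding_preserves_order(self):
        X = np.linspace(0, 9, 10)[:, None]
        m = fit_isomap(X, k=1, d=1)
        order = np.argsort(m.embedding[:, 0])
        assert order.tolist() in ([*range(10)], [*range(9, -1, -1)])

    def test_rigid_transform_invariance_of_distances(self, rng):
        X = rng.standard_normal((30, 3))
        Q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        m1 = fit_isomap(X, k=6)
        m2 = fit_isomap(X @ Q + 5.0, k=6)
        np.testing.assert_allclose(pdist(m1.embedding), pdist(m2.embedding), atol=1e-8)

    def test_insufficient_positive_eigenvalues_rejected(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])  # two points: 1 positive eigenpair
        with pytest.raises(ConfigurationError, match="eigenvalue"):
            embed(D, d=2)

    def test_agrees_with_sklearn_isomap(self, rng):
        """Independent implementation check: same geodesic-MDS geometry."""
        from sklearn.manifold import Isomap as SkIsomap

        X = rng.standard_normal((60, 4))
        ours = fit_isomap(X, k=8)
        sk = SkIsomap(n_neighbors=8, n_components=2).fit(X)
        np.testing.assert_allclose(
            pdist(ours.embedding), pdist(sk.embedding_), atol=1e-6
        )


class TestOutOfSample:
    def test_training_points_reproduce_their_embedding(self, rng):
        P = rng.random((50, 2)) * 8
        B = np.linalg.qr(rng.standard_normal((6, 6)))[0][:, :2]
        X = P @ B.T
        m = fit_isomap(X, k=10)
        oos = out_of_sample(m, X)
        scale = np.linalg.norm(m.embedding, axis=1).max()
        assert np.linalg.norm(oos - m.embedding, axis=1).max() / scale < 1e-3

    def test_midpoint_lands_near_midpoint(self, rng):
        P = rng.random((50, 2)) * 8
        B = np.linalg.qr(rng.standard_normal((6, 6)))[0][:, :2]
        X = P @ B.T
        m = fit_isomap(X, k=10)
        i, j = 0, int(np.argmin(np.linalg.norm(X[1:] - X[0], axis=1))) + 1
        mid = out_of_sample(m, (X[i] + X[j]) / 2)
        expected = (m.embedding[i] + m.embedding[j]) / 2
        assert np.linalg.norm(mid - expected) < 0.5

    def test_duplicated_point_matches_reembedding_oracle(self, rng):
        """Projecting x equals (up to alignment) re-fitting with x included."""
        P = rng.random((40, 2)) * 8
        B = np.linalg.qr(rng.standard_normal((5, 5)))[0][:, :2]
        X = P @ B.T
        x_new = X[7] + 1e-9  # essentially a duplicate of a training compound
        m = fit_isomap(X, k=8)
        proj = out_of_sample(m, x_new)
        assert np.linalg.norm(proj - m.embedding[7]) < 1e-3

    def test_dimension_and_finiteness_validation(self, rng):
        X = rng.standard_normal((20, 3))
        m = fit_isomap(X, k=4)
        with pytest.raises(ConfigurationError, match="features"):
            out_of_sample(m, np.zeros(5))
        with pytest.raises(ConfigurationError, match="finite"):
            out_of_sample(m, np.array([np.nan, 0.0, 0.0]))

    def test_printed_scaling_flag_changes_convention(self, rng):
        X = rng.standard_normal((25, 3))
        m = fit_isomap(X, k=5)
        a = out_of_sample(m, X[:3])
        m.scaling = "printed"
        b = out_of_sample(m, X[:3])
        # printed variant divides by an extra sqrt(lambda): columns rescale
        ratio = a / b
        np.testing.assert_allclose(ratio[:, 0], np.sqrt(m.eigenvalues[0]), rtol=1e-6)


class TestSupervisedFit:
    def test_single_class_supervised_equals_unsupervised_neighbors(self, rng):
        """With one class only, the same-class transform is monotone in d,
        so kNN sets match the unsupervised ones."""
        X = rng.standard_normal((30, 4))
        y = np.zeros(30, dtype=int)
        data = cg.LabeledDataset(ids=[str(i) for i in range(30)], X=X, y=y)
        sup, mask_s, _, _ = build_graph(X, y, k=5, supervised=True, alpha=0.0)
        uns, mask_u, _, _ = build_graph(X, None, k=5)
        assert mask_s.sum() == mask_u.sum()
        np.testing.assert_array_equal(sup > 0, uns > 0)

    def test_two_class_swiss_roll_scores_high(self, swiss_roll):
        data, _ = swiss_roll
        m = fit_s_isomap(data, k=8, alpha=1.0)
        labels = m.labels
        report = cg.quality_report(m.embedding, labels)
        assert min(report.gamma, report.dsc, report.dc) >= 0.9
        # both classes survive the largest-component restriction
        assert len(np.unique(labels)) == 2
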