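"""GTM training, responsibilities, projection, Bayes classification."""

import numpy as np
import pytest
from scipy.special import logsumexp

import chemography as cg
from chemography.data import ConfigurationError
from chemography.gtm import GTMModel


class TestFit:
    def test_single_component_mle(self, rng):
        """K=1: the mixture degenerates to one Gaussian at the centroid with
        1/beta the mean squared per-dimension deviation."""
        X = rng.standard_normal((50, 4)) * 2 + 5
        m = cg.fit_gtm(X, K=1, M=1, seed=0)
        np.testing.assert_allclose(m.manifold()[0], X.mean(axis=0), atol=1e-10)
        msd = ((X - X.mean(axis=0)) ** 2).mean()
        assert 1.0 / m.beta == pytest.approx(msd, rel=1e-8)

    def test_log_likelihood_trace_non_decreasing(self, small_gtm):
        diffs = np.diff(small_gtm.ll_trace)
        assert np.all(diffs >= -1e-8)

    def test_blobs_occupy_distinct_latent_nodes(self, blob_data):
        """Well-separated blobs concentrate responsibility on different nodes."""
        m = cg.fit_gtm(blob_data.X, K=4, M=4, seed=0)
        R = cg.responsibilities(m, blob_data.X)
        top0 = np.bincount(R[blob_data.y == 0].argmax(axis=1), minlength=4)
        top1 = np.bincount(R[blob_data.y == 1].argmax(axis=1), minlength=4)
        assert top0.argmax() != top1.argmax()

    def test_duplicating_every_compound_leaves_fit_unchanged(self, blob_data):
        m1 = cg.fit_gtm(blob_data.X, K=16, M=4, seed=0, max_iter=40)
        m2 = cg.fit_gtm(np.vstack([blob_data.X, blob_data.X]), K=16, M=4, seed=0, max_iter=40)
        assert np.abs(m1.W - m2.W).max() < 1e-6
        assert abs(m1.beta - m2.beta) < 1e-6 * m1.beta

    def test_non_square_grid_rejected(self, blob_data):
        with pytest.raises(ConfigurationError, match="perfect square"):
            cg.fit_gtm(blob_data.X, K=10, M=4)

    def test_oversized_grid_warns(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.warns(UserWarning, match="exceeds"):
            cg.fit_gtm(X, K=9, M=4, max_iter=5)

    def test_determinism_given_seed(self, blob_data):
        a = cg.fit_gtm(blob_data.X, K=9, M=4, seed=7, max_iter=20)
        b = cg.fit_gtm(blob_data.X, K=9, M=4, seed=7, max_iter=20)
        np.testing.assert_array_equal(a.W, b.W)
        assert a.beta == b.beta


class TestResponsibilities:
    def test_rows_sum_to_one(self, small_gtm, blob_data):
        R = cg.responsibilities(small_gtm, blob_data.X)
        np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-10)
        assert R.min() >= 0 and R.max() <= 1

    def test_single_node_gives_unit_responsibility(self, rng):
        X = rng.standard_normal((20, 3))
        m = cg.fit_gtm(X, K=1, M=1, seed=0)
        R = cg.responsibilities(m, X)
        np.testing.assert_allclose(R, 1.0)

    def test_equidistant_probe_splits_evenly(self):
        """A probe equidistant from two projected centers gets r = (1/2, 1/2)."""
        m = _toy_model(centers=np.array([[-1.0, 0.0], [1.0, 0.0]]))
        R = cg.responsibilities(m, np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(R[0], [0.5, 0.5], atol=1e-12)

    def test_matches_direct_gaussian_kernel_evaluation(self):
        """Hand evaluation with the explicit Gaussian kernel on 3 nodes."""
        centers = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        m = _toy_model(centers=centers, beta=1.7)
        probe = np.array([[0.3, 0.4]])
        logw = -0.5 * 1.7 * ((probe - centers) ** 2).sum(axis=1)
        expected = np.exp(logw - logsumexp(logw))
        np.testing.assert_allclose(cg.responsibilities(m, probe)[0], expected, atol=1e-12)

    def test_dimension_mismatch_raises(self, small_gtm):
        with pytest.raises(ConfigurationError, match="columns"):
            cg.responsibilities(small_gtm, np.zeros((3, 9)))


def _toy_model(centers: np.ndarray, beta: float = 1.0) -> GTMModel:
    """Model whose manifold points equal `centers` exactly (identity-ish RBF)."""
    K = len(centers)
    side = int(round(np.sqrt(K))) if int(round(np.sqrt(K))) ** 2 == K else K
    from chemography.gtm import _square_grid

    latent = _square_grid(2)[:K] if K <= 4 else _square_grid(side)
    model = GTMModel(
        latent_grid=latent[:K],
        rbf_centers=latent[:K],
        rbf_width=1.0,
        W=np.zeros((K + 1, centers.shape[1])),
        beta=beta,
    )
    Phi = model.phi()
    model.W = np.linalg.lstsq(Phi, centers, rcond=None)[0]
    assert np.abs(model.manifold() - centers).max() < 1e-9
    return model


class TestProjection:
    def test_uniform_responsibilities_project_to_origin(self, rng):
        """Symmetric grid: equal responsibilities average to (0, 0)."""
        X = rng.standard_normal((30, 3))
        m = cg.fit_gtm(X, K=16, M=4, seed=0, max_iter=5)
        R = np.full((1, 16), 1 / 16)
        np.testing.assert_allclose(R @ m.latent_grid, [[0.0, 0.0]], atol=1e-12)

    def test_concentrated_responsibility_mean_equals_mode(self, blob_data, small_gtm):
        R = cg.responsibilities(small_gtm, blob_data.X)
        concentrated = R.max(axis=1) > 0.999
        if concentrated.any():
            mean_p = cg.project(small_gtm, blob_data.X, mode="mean").coords
            mode_p = cg.project(small_gtm, blob_data.X, mode="mode").coords
            np.testing.assert_allclose(
                mean_p[concentrated], mode_p[concentrated], atol=1e-2
            )

    def test_mean_projection_is_responsibility_weighted_sum(self, small_gtm, blob_data):
        probe = blob_data.X[:5]
        R = cg.responsibilities(small_gtm, probe)
        expected = R @ small_gtm.latent_grid
        np.testing.assert_allclose(
            cg.project(small_gtm, probe).coords, expected, atol=1e-12
        )

    def test_coordinates_stay_in_latent_rectangle(self, small_gtm, blob_data):
        coords = cg.project(small_gtm, blob_data.X).coords
        assert np.abs(coords).max() <= 1.0 + 1e-12


class TestBayesClassification:
    def test_priors_are_class_frequencies(self):
        data = cg.gaussian_classes(n_per_class=(60, 40), dim=3, separation=5, seed=0)
        model = cg.fit_class_density(data, K=4, M=4, max_iter=10)
        assert model.priors[0] == pytest.approx(0.6)
        assert model.priors[1] == pytest.approx(0.4)

    def test_single_class_data_rejected(self, rng):
        data = cg.LabeledDataset(
            ids=[str(i) for i in range(10)],
            X=rng.standard_normal((10, 3)),
            y=np.zeros(10, dtype=int),
        )
        with pytest.raises(ConfigurationError):
            cg.fit_class_density(data, K=4, M=4)

    def test_posterior_formula_direct_case(self):
        """p(t|C1)=0.3, p(t|C2)=0.1, equal priors -> P(C1|t)=0.75."""
        from chemography.gtm import ClassDensityModel, classify

        class Fixed:
            def __init__(self, dens):
                self.dens = dens

            def log_density(self, T):
                return np.full(len(np.atleast_2d(T)), np.log(self.dens))

        model = ClassDensityModel.__new__(ClassDensityModel)
        model.models = {0: Fixed(0.3), 1: Fixed(0.1)}
        model.priors = {0: 0.5, 1: 0.5}
        model.classes = [0, 1]
        model.pca = None
        probs, pred, flagged = classify(model, np.zeros((1, 2)))
        np.testing.assert_allclose(probs[0], [0.75, 0.25], atol=1e-12)
        assert pred[0] == 0 and not flagged[0]

    def test_identical_densities_return_priors(self):
        """Equal class-conditional densities reduce the posterior to the prior."""
        data = cg.gaussian_classes(n_per_class=(90, 60), dim=3, separation=0.0, seed=3)
        model = cg.fit_class_density(data, K=1, M=1, max_iter=60)
        probe = np.zeros((4, 3))
        probs, _, _ = cg.classify(model, probe)
        np.testing.assert_allclose(probs[:, 0], 0.6, atol=0.06)

    def test_zero_density_probe_falls_back_to_priors(self):
        data = cg.gaussian_classes(n_per_class=(30, 20), dim=3, separation=4, seed=0)
        model = cg.fit_class_density(data, K=4, M=4, max_iter=20)
        far = np.full((1, 3), 1e6)
        probs, _, flagged = cg.classify(model, far)
        assert flagged[0]
        np.testing.assert_allclose(probs[0], [0.6, 0.4], atol=1e-12)

    def test_posteriors_normalized(self, blob_data):
        model = cg.fit_class_density(blob_data, K=9, M=4, max_iter=20)
        probs, pred, _ = cg.classify(model, blob_data.X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        assert (pred == blob_data.y).mean() > 0.95
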