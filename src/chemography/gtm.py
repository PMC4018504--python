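"""Generative Topographic Mapping.

A GTM models a point cloud in descriptor space R^D as the image of a
regular K-node grid in a 2-D latent rectangle [-1, 1]^2, pushed through an
RBF network y(x) = W phi(x) and blurred by an isotropic Gaussian of inverse
variance beta.  The mixture

    p(t) = (1/K) sum_k N(t | y(x_k), beta^{-1} I)

is fitted by expectation-maximization on the log-likelihood

    L(W, beta) = sum_n ln (1/K) sum_k p(t_n | x_k, W, beta),

which is non-decreasing across iterations.  The latent grid plays the role
of a probabilistic self-organizing map: the responsibility r_kn is the
posterior probability that node k generated compound n, and compounds are
drawn on the map either at their responsibility-weighted mean latent
position or at the node of maximal responsibility.

Classification follows Bayes: one GTM per activity class C_k provides the
class-conditional density p(t | C_k), combined with priors P(C_k) = N_k/N_tot
into posterior class-membership probabilities.

All density work is done in log space (log-sum-exp), which keeps the model
usable at the hundreds of descriptor dimensions typical of this domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data import ConfigurationError, LabeledDataset, PCATransform, Projection2D, fit_pca

_LOG_2PI = float(np.log(2.0 * np.pi))


def _square_grid(side: int) -> np.ndarray:
    """`side` x `side` regular grid on [-1, 1]^2, row-major from (-1,-1)."""
    if side == 1:
        return np.zeros((1, 2))
    axis = np.linspace(-1.0, 1.0, side)
    gx, gy = np.meshgrid(axis, axis)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _as_side(count: int, name: str) -> int:
    side = int(round(np.sqrt(count)))
    if side * side != count:
        raise ConfigurationError(f"{name}={count} must be a perfect square")
    return side


@dataclass
class GTMModel:
    """Fitted GTM: latent grid, RBF basis, weights W, noise precision beta."""

    latent_grid: np.ndarray       # (K, 2)
    rbf_centers: np.ndarray       # (M, 2)
    rbf_width: float
    W: np.ndarray                 # (M + 1, D) -- last row is the bias
    beta: float
    pca: PCATransform | None = None
    ll_trace: list = field(default_factory=list)
    ridge: float = 0.0

    @property
    def K(self) -> int:
        return self.latent_grid.shape[0]

    @property
    def grid_side(self) -> int:
        return int(round(np.sqrt(self.K)))

    def phi(self, latent_points: np.ndarray | None = None) -> np.ndarray:
        """RBF design matrix with bias column, evaluated on latent points."""
        x = self.latent_grid if latent_points is None else np.atleast_2d(latent_points)
        sq = ((x[:, None, :] - self.rbf_centers[None, :, :]) ** 2).sum(axis=2)
        basis = np.exp(-sq / (2.0 * self.rbf_width**2))
        return np.column_stack([basis, np.ones(len(x))])

    def manifold(self) -> np.ndarray:
        """Projections y(x_k) = W phi(x_k) of the latent nodes into data space."""
        return self.phi() @ self.W

    def _prepare(self, T: np.ndarray) -> np.ndarray:
        T = np.atleast_2d(np.asarray(T, dtype=float))
        if self.pca is not None:
            if T.shape[1] == self.pca.mean.shape[0]:
                T = self.pca.transform(T)
            elif T.shape[1] != self.W.shape[1]:
                raise ConfigurationError(
                    f"input has {T.shape[1]} columns; model expects "
                    f"{self.pca.mean.shape[0]} (raw) or {self.W.shape[1]} (reduced)"
                )
        elif T.shape[1] != self.W.shape[1]:
            raise ConfigurationError(
                f"input has {T.shape[1]} columns; model data space is {self.W.shape[1]}-D"
            )
        return T

    def log_component_densities(self, T: np.ndarray) -> np.ndarray:
        """(N, K) matrix of ln p(t_n | x_k, W, beta)."""
        T = self._prepare(T)
        Y = self.manifold()
        d = Y.shape[1]
        sq = (
            (T**2).sum(axis=1)[:, None]
            - 2.0 * T @ Y.T
            + (Y**2).sum(axis=1)[None, :]
        )
        np.maximum(sq, 0.0, out=sq)
        return 0.5 * d * (np.log(self.beta) - _LOG_2PI) - 0.5 * self.beta * sq

    def log_density(self, T: np.ndarray) -> np.ndarray:
        """ln p(t_n) under the mixture (uniform node prior p(x_k) = 1/K)."""
        logp = self.log_component_densities(T)
        return logsumexp(logp, axis=1) - np.log(self.K)

    def log_likelihood(self, T: np.ndarray) -> float:
        return float(self.log_density(T).sum())


def responsibilities(model: GTMModel, T: np.ndarray) -> np.ndarray:
    """Posterior node-membership probabilities r_kn, returned as (N, K).

    r_kn = p(x_k | t_n, W, beta) with uniform latent prior 1/K; rows sum to 1.
    """
    logp = model.log_component_densities(T)
    logp -= logsumexp(logp, axis=1, keepdims=True)
    return np.exp(logp)


def project(
    model: GTMModel,
    T: np.ndarray,
    mode: str = "mean",
    ids: list[str] | None = None,
    method_tag: str = "gtm",
) -> Projection2D:
    """Map compounds onto the latent rectangle.

    ``mode="mean"`` gives the responsibility-weighted mean latent position
    Sigma_k r_kn x_k; ``mode="mode"`` the latent node of maximal
    responsibility (ties to the lower node index).
    """
    R = responsibilities(model, T)
    if mode == "mean":
        coords = R @ model.latent_grid
    elif mode == "mode":
        coords = model.latent_grid[np.argmax(R, axis=1)]
    else:
        raise ConfigurationError(f"unknown projection mode {mode!r}")
    if ids is None:
        ids = [str(i) for i in range(len(coords))]
    return Projection2D(ids=ids, coords=coords, method_tag=method_tag)


def _initial_model(
    T: np.ndarray,
    grid_side: int,
    rbf_side: int,
    width_factor: float,
    ridge: float,
    rng: np.random.Generator,
    noise_scale: float = 1e-2,
) -> GTMModel:
    """PCA-plane initialization (standard GTM practice) plus seeded noise."""
    n, d = T.shape
    latent = _square_grid(grid_side)
    centers = _square_grid(rbf_side)
    spacing = 2.0 / (rbf_side - 1) if rbf_side > 1 else 2.0
    width = width_factor * spacing

    mean = T.mean(axis=0)
    Tc = T - mean
    cov = (Tc.T @ Tc) / n
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    n_dir = min(2, d)
    directions = evecs[:, :n_dir] * np.sqrt(np.maximum(evals[:n_dir], 1e-12))
    targets = latent[:, :n_dir] @ directions.T + mean

    model = GTMModel(
        latent_grid=latent,
        rbf_centers=centers,
        rbf_width=width,
        W=np.zeros((rbf_side**2 + 1, d)),
        beta=1.0,
        ridge=ridge,
    )
    Phi = model.phi()
    reg = max(ridge, 1e-8) * np.eye(Phi.shape[1])
    reg[-1, -1] = 0.0  # bias unpenalized
    W = np.linalg.solve(Phi.T @ Phi + reg, Phi.T @ targets)
    scale = float(np.abs(W).max()) or 1.0
    W = W + noise_scale * scale * rng.standard_normal(W.shape)
    model.W = W

    # beta^{-1}: the larger of the next residual PCA variance and half the
    # squared typical spacing between adjacent projected nodes.
    resid = float(evals[n_dir]) if d > n_dir else 0.0
    Y = model.manifold()
    if len(Y) > 1:
        dmat = np.linalg.norm(Y[:, None, :] - Y[None, :, :], axis=2)
        np.fill_diagonal(dmat, np.inf)
        inter = float(np.mean(np.min(dmat, axis=1))) / 2.0
    else:
        inter = 0.0
    var0 = max(resid, inter**2, float(Tc.var()) * 1e-3, 1e-6)
    model.beta = 1.0 / var0
    return model


def fit_gtm(
    data,
    K: int = 100,
    M: int = 16,
    width_factor: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-5,
    ridge: float = 0.0,
    seed: int = 0,
    pca_components: int | None = None,
) -> GTMModel:
    """Train a GTM by EM.

    Parameters
    ----------
    data : LabeledDataset or matrix
    K : number of latent nodes (perfect square; grid of sqrt(K) per side)
    M : number of RBF centers (perfect square)
    width_factor : RBF width as a multiple of the center spacing
    tol : relative log-likelihood change that stops EM
    ridge : optional per-compound M-step weight decay on W (bias row
        unpenalized); the default 0 keeps the plain EM update, whose
        log-likelihood trace is exactly non-decreasing.  A singular
        M-step system is resolved automatically with a warning.
    pca_components : optional PCA pre-reduction stored on the model

    The per-iteration log-likelihood trace is stored on ``model.ll_trace``.
    """
    X = data.X if isinstance(data, LabeledDataset) else np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("GTM needs a 2-D matrix with at least 2 rows")
    grid_side = _as_side(K, "K")
    rbf_side = _as_side(M, "M")
    if K > X.shape[0]:
        warnings.warn(f"K={K} exceeds the number of compounds ({X.shape[0]})")

    pca = None
    T = X
    if pca_components is not None:
        pca = fit_pca(X, pca_components)
        T = pca.transform(X)

    rng = np.random.default_rng(seed)
    model = _initial_model(T, grid_side, rbf_side, width_factor, ridge, rng)
    n, d = T.shape
    Phi = model.phi()
    # per-compound weight decay: duplicating the dataset leaves the EM
    # fixed point (and hence the fitted W, beta) unchanged
    reg = ridge * n * np.eye(Phi.shape[1])
    reg[-1, -1] = 0.0

    trace: list[float] = []
    for _ in range(max_iter):
        logp = model.log_component_densities(T)
        ll = float((logsumexp(logp, axis=1) - np.log(model.K)).sum())
        trace.append(ll)

        R = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))  # (N, K)
        G = R.sum(axis=0)                                          # (K,)
        A = Phi.T @ (G[:, None] * Phi) + (reg / model.beta)
        B = Phi.T @ (R.T @ T)
        try:
            W_new = np.linalg.solve(A, B)
            if not np.all(np.isfinite(W_new)):
                raise np.linalg.LinAlgError("non-finite solution")
        except np.linalg.LinAlgError:
            # normal equations are consistent, so the least-squares
            # solution still maximizes the expected complete-data
            # log-likelihood and EM monotonicity is preserved
            warnings.warn("singular M-step system; resolved by least-squares ridge")
            W_new = np.linalg.lstsq(A, B, rcond=None)[0]
        model.W = W_new

        Y = model.manifold()
        sq = (
            (T**2).sum(axis=1)[:, None]
            - 2.0 * T @ Y.T
            + (Y**2).sum(axis=1)[None, :]
        )
        np.maximum(sq, 0.0, out=sq)
        resid = float((R * sq).sum())
        # a perfectly interpolated dataset (possible when K, M >= N) drives
        # the noise variance to zero; cap the precision instead of overflowing
        model.beta = (n * d) / max(resid, n * d * 1e-12)

        if len(trace) >= 2:
            prev = trace[-2]
            if abs(trace[-1] - prev) < tol * (abs(prev) + 1e-12):
                break

    trace.append(model.log_likelihood(T))
    model.ll_trace = trace
    model.pca = pca
    return model


@dataclass
class ClassDensityModel:
    """Bayesian classifier from one GTM density per activity class."""

    models: dict[int, GTMModel]
    priors: dict[int, float]
    pca: PCATransform | None = None
    classes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = sorted(self.models)
        total = sum(self.priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("class priors must sum to 1")


def fit_class_density(
    data: LabeledDataset,
    pca_components: int | None = None,
    **gtm_params,
) -> ClassDensityModel:
    """One GTM per class C_k plus priors P(C_k) = N_k / N_tot.

    A shared PCA (fitted on the pooled data) keeps the per-class densities
    comparable in one common reduced space.
    """
    if data.y is None:
        raise ConfigurationError("class-density GTM needs labels")
    counts = data.class_counts()
    if len(counts) < 2:
        raise ConfigurationError("need at least two classes")
    if min(counts.values()) < 2:
        raise ConfigurationError("every class needs at least 2 compounds")

    pca = None
    X = data.X
    if pca_components is not None:
        pca = fit_pca(X, pca_components)
        X = pca.transform(X)

    models = {}
    for cls in sorted(counts):
        models[cls] = fit_gtm(X[data.y == cls], **gtm_params)
    priors = {cls: cnt / data.n for cls, cnt in counts.items()}
    return ClassDensityModel(models=models, priors=priors, pca=pca)


def classify(model: ClassDensityModel, T: np.ndarray):
    """Posterior class probabilities P(C_k | t) and argmax class per compound.

    Returns ``(posteriors, predicted, out_of_density)``; when every class
    density underflows for a compound the posterior falls back to the priors
    and the compound is flagged out-of-density.
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if model.pca is not None and T.shape[1] == model.pca.mean.shape[0]:
        T = model.pca.transform(T)
    classes = model.classes
    log_joint = np.column_stack(
        [model.models[c].log_density(T) + np.log(model.priors[c]) for c in classes]
    )
    out = logsumexp(log_joint, axis=1)
    posteriors = np.exp(log_joint - out[:, None])

    floor = np.log(np.finfo(float).tiny)
    flagged = np.max(log_joint, axis=1) < floor
    if flagged.any():
        prior_row = np.array([model.priors[c] for c in classes])
        posteriors[flagged] = prior_row
    predicted = np.array([classes[i] for i in np.argmax(posteriors, axis=1)])
    return posteriors, predicted, flagged
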