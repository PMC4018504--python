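"""Isomap and supervised Isomap with an out-of-sample projection.

Isomap embeds compounds so that geodesic distances -- shortest paths on a
k-nearest-neighbor graph -- are preserved by classical MDS: with D_geo the
geodesic matrix, the Gram matrix tau(D) = -1/2 H D^2 H (H the centering
matrix) is eigendecomposed and the top-d eigenpairs give the coordinates
sqrt(lambda_k) * v_k.

The supervised variant replaces the Euclidean distance d in the graph
construction by the class-aware dissimilarity

    D(x_i, x_j) = 1 - exp(-d^2 / beta)         if y_i == y_j
                  exp(d^2 / beta) - alpha      otherwise,

with beta a density scale (default: mean pairwise Euclidean distance) and
alpha in [0, 1] giving close cross-class pairs a chance to stay close.  An
auxiliary factor beta_1 replaces beta by beta_1 * beta when d^2/beta would
otherwise overflow.

External compounds are mapped without refitting: the dissimilarities to
the k nearest training compounds stand in for their geodesics, geodesics
to all remaining training compounds follow by relaxation through those
neighbors, and the coordinates come from the Nystrom form

    e_k(x) = 1/(2 sqrt(lambda_k)) * sum_i v_ki (E_x'[D^2(x', x_i)] - D^2(x_i, x)).

With this scaling a training compound fed back through the projector lands
on its training embedding (the ``scaling="printed"`` flag switches to a
1/(2 lambda_k) divisor for comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import cdist, pdist, squareform

from .data import ConfigurationError, LabeledDataset, Projection2D


def supervised_dissimilarity(
    d, same_class, alpha: float = 0.3, beta_s: float = 1.0
):
    """Class-aware dissimilarity from a Euclidean distance (vectorized).

    Same class: 1 - exp(-d^2/beta); different class: exp(d^2/beta) - alpha.
    """
    if beta_s <= 0:
        raise ConfigurationError("beta_s must be positive")
    d2 = np.asarray(d, dtype=float) ** 2 / beta_s
    same = np.asarray(same_class, dtype=bool)
    return np.where(same, 1.0 - np.exp(-d2), np.exp(d2) - alpha)


@dataclass
class IsomapModel:
    """Fitted (s-)Isomap: graph, geodesics, eigensystem, 2-D embedding."""

    train_X: np.ndarray                 # retained training compounds
    embedding: np.ndarray               # (n_retained, d_out)
    eigenvalues: np.ndarray             # top d_out, descending
    eigenvectors: np.ndarray            # (n_retained, d_out), unit columns
    D_geo: np.ndarray                   # geodesic distances on retained set
    k: int
    supervised: bool = False
    labels: np.ndarray | None = None    # training labels of retained compounds
    alpha: float = 0.3
    beta_s: float = 1.0
    beta1: float = 1.0
    component_mask: np.ndarray | None = None  # retained rows of the input
    dropped_ids: list = field(default_factory=list)
    ids: list = field(default_factory=list)
    scaling: str = "sqrt"

    @property
    def n_components(self) -> int:
        return self.embedding.shape[1]


def _pairwise_dissimilarity(X, y, supervised, alpha, beta_s, beta1):
    d = squareform(pdist(X))
    if not supervised:
        return d
    if y is None:
        raise ConfigurationError("supervised graph construction needs labels")
    same = y[:, None] == y[None, :]
    return supervised_dissimilarity(d, same, alpha=alpha, beta_s=beta1 * beta_s)


def _default_beta(X) -> float:
    d = pdist(X)
    return float(d.mean()) if d.size else 1.0


def _default_beta1(X, beta_s, guard: float = 50.0) -> float:
    """Scale-compensating factor when d^2/beta would overflow the exponential."""
    d2 = pdist(X) ** 2
    if d2.size == 0:
        return 1.0
    ratio = float(d2.mean()) / beta_s
    return max(1.0, ratio / guard)


def build_graph(
    X: np.ndarray,
    labels: np.ndarray | None,
    k: int,
    supervised: bool = False,
    alpha: float = 0.3,
    beta_s: float | None = None,
    beta1: float | None = None,
):
    """kNN graph (symmetrized union) restricted to its largest component.

    Returns ``(weights, component_mask, beta_s, beta1)`` where ``weights``
    is the dense adjacency over retained compounds (0 = no edge) and
    ``component_mask`` flags the rows of ``X`` that were kept.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k >= n:
        raise ConfigurationError(f"k={k} must be smaller than the number of compounds ({n})")
    if supervised and not 0.0 <= alpha <= 1.0:
        raise ConfigurationError("alpha must lie in [0, 1] (non-negative edge weights)")
    if beta_s is None:
        beta_s = _default_beta(X)
    if beta1 is None:
        beta1 = _default_beta1(X, beta_s) if supervised else 1.0

    D = _pairwise_dissimilarity(X, labels, supervised, alpha, beta_s, beta1)
    np.fill_diagonal(D, np.inf)
    # stable kNN: ties broken by compound index
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), D), axis=1)
    adj = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    cols = order[:, :k].ravel()
    adj[rows, cols] = D[rows, cols]
    adj = np.maximum(adj, adj.T)  # undirected union of kNN lists

    n_comp, assignment = connected_components(csr_matrix(adj), directed=False)
    if n_comp > 1:
        sizes = np.bincount(assignment)
        keep_comp = int(np.argmax(sizes))
        mask = assignment == keep_comp
        adj = adj[np.ix_(mask, mask)]
    else:
        mask = np.ones(n, dtype=bool)
    return adj, mask, float(beta_s), float(beta1)


def geodesic_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths (Dijkstra) over a connected weighted graph."""
    graph = csr_matrix(adj)
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ConfigurationError(
            "graph is disconnected; restrict to the largest component first"
        )
    D = dijkstra(graph, directed=False)
    return D


def embed(D_geo: np.ndarray, d: int = 2):
    """Classical MDS of a geodesic matrix: top-d eigenpairs of -1/2 H D^2 H.

    Returns ``(coords, eigenvalues, eigenvectors)``; coordinates are the
    unit eigenvectors scaled by sqrt(lambda), centered at the origin.
    """
    D_geo = np.asarray(D_geo, dtype=float)
    n = D_geo.shape[0]
    if D_geo.shape != (n, n) or not np.allclose(D_geo, D_geo.T, atol=1e-8):
        raise ConfigurationError("D_geo must be square and symmetric")
    D2 = D_geo**2
    H = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * H @ D2 @ H
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if n <= d or evals[d - 1] <= 1e-12:
        n_pos = int(np.sum(evals > 1e-12))
        raise ConfigurationError(
            f"only {n_pos} positive eigenvalue(s); cannot build a {d}-D embedding"
        )
    evals_d = evals[:d].copy()
    evecs_d = evecs[:, :d].copy()
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for j in range(d):
        i = int(np.argmax(np.abs(evecs_d[:, j])))
        if evecs_d[i, j] < 0:
            evecs_d[:, j] = -evecs_d[:, j]
    coords = evecs_d * np.sqrt(evals_d)
    return coords, evals_d, evecs_d


def fit_isomap(
    data,
    k: int = 8,
    d: int = 2,
    supervised: bool = False,
    alpha: float = 0.3,
    beta_s: float | None = None,
    beta1: float | None = None,
) -> IsomapModel:
    """Fit (s-)Isomap: graph -> geodesics -> classical MDS.

    ``data`` is a LabeledDataset (labels required when supervised) or a
    plain matrix.  Compounds outside the largest connected component are
    dropped and reported on ``model.dropped_ids``.
    """
    if isinstance(data, LabeledDataset):
        X, y, ids = data.X, data.y, list(data.ids)
    else:
        X = np.asarray(data, dtype=float)
        y, ids = None, [str(i) for i in range(len(X))]

    adj, mask, beta_s, beta1 = build_graph(
        X, y, k, supervised=supervised, alpha=alpha, beta_s=beta_s, beta1=beta1
    )
    dropped = [i for i, keep in zip(ids, mask) if not keep]
    if dropped:
        warnings.warn(
            f"{len(dropped)} compound(s) outside the largest connected component were dropped"
        )
    D_geo = geodesic_distances(adj)
    coords, evals, evecs = embed(D_geo, d=d)
    return IsomapModel(
        train_X=X[mask],
        embedding=coords,
        eigenvalues=evals,
        eigenvectors=evecs,
        D_geo=D_geo,
        k=k,
        supervised=supervised,
        labels=None if y is None else y[mask],
        alpha=alpha,
        beta_s=beta_s,
        beta1=beta1,
        component_mask=mask,
        dropped_ids=dropped,
        ids=[i for i, keep in zip(ids, mask) if keep],
    )


def fit_s_isomap(data, k: int = 8, d: int = 2, alpha: float = 0.3,
                 beta_s: float | None = None, beta1: float | None = None) -> IsomapModel:
    """Supervised Isomap (class-aware dissimilarity in the graph step)."""
    return fit_isomap(data, k=k, d=d, supervised=True, alpha=alpha,
                      beta_s=beta_s, beta1=beta1)


def _new_point_dissimilarity(model: IsomapModel, x: np.ndarray) -> np.ndarray:
    """Dissimilarity from an unlabeled external compound to every training compound.

    The new compound's class is unknown at projection time, so the
    same-class branch of the supervised dissimilarity is used (nearby
    compounds dominate the projection and their relative placement depends
    little on label information).
    """
    d = cdist(x[None, :], model.train_X)[0]
    if not model.supervised:
        return d
    return supervised_dissimilarity(
        d, np.ones_like(d, dtype=bool), alpha=model.alpha,
        beta_s=model.beta1 * model.beta_s,
    )


def out_of_sample(model: IsomapModel, x: np.ndarray, k: int | None = None) -> np.ndarray:
    """Project external compounds onto a fitted embedding (Nystrom form).

    ``x`` may be a single vector or a matrix; returns matching coordinates.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return out_of_sample(model, x[None, :], k=k)[0]
    if x.shape[1] != model.train_X.shape[1]:
        raise ConfigurationError(
            f"compound has {x.shape[1]} features; model space is {model.train_X.shape[1]}-D"
        )
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("external compound has non-finite entries")
    if model.eigenvalues.shape[0] < model.n_components or np.any(model.eigenvalues <= 0):
        raise ConfigurationError("insufficient positive eigenpairs for projection")
    k = model.k if k is None else k

    col_mean_sq = (model.D_geo**2).mean(axis=0)
    coords = np.empty((x.shape[0], model.n_components))
    for r, row in enumerate(x):
        diss = _new_point_dissimilarity(model, row)
        nbrs = np.lexsort((np.arange(len(diss)), diss))[:k]
        # geodesic to a neighbor = its (small) dissimilarity; to anyone else,
        # relaxation through the nearest neighbors
        g = np.min(diss[nbrs, None] + model.D_geo[nbrs, :], axis=0)
        proj = model.eigenvectors.T @ (col_mean_sq - g**2)
        if model.scaling == "printed":
            coords[r] = proj / (2.0 * model.eigenvalues)
        else:
            coords[r] = proj / (2.0 * np.sqrt(model.eigenvalues))
    return coords


def project_isomap(model: IsomapModel, T: np.ndarray,
                   ids: list[str] | None = None) -> Projection2D:
    """Out-of-sample projection packaged as a 2-D map."""
    coords = out_of_sample(model, np.atleast_2d(np.asarray(T, dtype=float)))
    if ids is None:
        ids = [str(i) for i in range(len(coords))]
    tag = "s-isomap" if model.supervised else "isomap"
    return Projection2D(ids=ids, coords=coords[:, :2], method_tag=tag)
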