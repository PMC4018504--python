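"""Supervised GTM: class-aware manifold training.

Starting from a converged unsupervised GTM, each supervised iteration has
two steps:

1. *Latent-point labeling.*  For every latent node k and each class j the
   class-mean responsibility S_j = (1/N_j) sum_{i in class j} r_ki is
   computed.  The node receives the label of the larger sum only when the
   margin exceeds a class-specific threshold

       thr'_c = thr + (N_other - N_c) / rho,

   where N_c counts the node's grid neighbors (8-connected) that carried
   label c on the previous iteration: neighbors of the same class lower the
   bar, opposite-class neighbors raise it, encouraging contiguous
   same-label patches.  Nodes that fail both margins stay unlabeled.

2. *Manifold movement.*  Each labeled node's data-space projection P is
   pulled toward same-class compounds and pushed from opposite-class ones:
   over all compounds with responsibility r_kn above the responsibility
   radius ``rr``, the signed displacement sum T = sum +-(t_n - P) is
   accumulated (minus for the opposite class) and the node's target becomes
   P' = P + T/N with N the number of contributing compounds.  The RBF
   network is then re-solved (same ridge least-squares system as the GTM
   M-step) with latent coordinates as inputs and the targets P'
   (unlabeled nodes keep their current projection).

Supervision moves only the manifold (W); the projection rule is exactly the
unsupervised one, so re-projecting a training compound reproduces its
training map position bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data import ConfigurationError, LabeledDataset, Projection2D
from .gtm import GTMModel, fit_gtm, project, responsibilities

UNLABELED = -1


@dataclass
class SGTMModel:
    """Supervised GTM: moved manifold plus per-latent-node class labels."""

    base: GTMModel
    latent_labels: np.ndarray  # (K,) values in {0, 1, UNLABELED}
    thr: float
    rho: float
    rr: float
    n_supervised_iters: int = 0


def _neighbor_lists(side: int) -> list[np.ndarray]:
    """8-connected (Moore) neighborhood on a side x side grid, row-major."""
    out = []
    for r in range(side):
        for c in range(side):
            nbrs = [
                rr_ * side + cc
                for rr_ in range(max(r - 1, 0), min(r + 2, side))
                for cc in range(max(c - 1, 0), min(c + 2, side))
                if (rr_, cc) != (r, c)
            ]
            out.append(np.array(nbrs, dtype=int))
    return out


def adjusted_threshold(thr: float, n_same: int, n_other: int, rho: float) -> float:
    """Neighbor-adjusted labeling threshold thr' = thr + (N_other - N_same)/rho."""
    return thr + (n_other - n_same) / rho


def label_latent_points(
    model: GTMModel,
    data: LabeledDataset,
    thr: float,
    rho: float,
    prev_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Assign each latent node a class label or leave it unlabeled.

    Node k gets class c iff S_c > S_other + thr'_c, with thr'_c adjusted by
    the previous iteration's labels of the node's grid neighbors.
    """
    if data.y is None:
        raise ConfigurationError("supervised labeling needs class labels")
    classes = np.unique(data.y)
    if len(classes) != 2:
        raise ConfigurationError(
            f"latent labeling is defined for exactly two classes, got {len(classes)}"
        )
    R = responsibilities(model, data.X)  # (N, K)
    S = np.vstack([R[data.y == c].mean(axis=0) for c in classes])  # (2, K)

    K = model.K
    if prev_labels is None:
        prev_labels = np.full(K, UNLABELED, dtype=int)
    neighbors = _neighbor_lists(model.grid_side)

    labels = np.full(K, UNLABELED, dtype=int)
    for k in range(K):
        counts = [int(np.sum(prev_labels[neighbors[k]] == c)) for c in classes]
        for idx, cls in enumerate(classes):
            other = 1 - idx
            thr_c = adjusted_threshold(thr, counts[idx], counts[other], rho)
            if S[idx, k] > S[other, k] + thr_c:
                labels[k] = cls
                break
    return labels


def movement_step(
    model: GTMModel,
    data: LabeledDataset,
    latent_labels: np.ndarray,
    rr: float,
    n_convention: str = "contributors",
) -> GTMModel:
    """Pull labeled manifold nodes toward their class and re-solve the RBF net.

    ``n_convention`` selects the divisor in P' = P + T/N: the number of
    contributing compounds (default, a mean signed displacement) or the
    total dataset size (``"total"``).
    """
    if data.y is None:
        raise ConfigurationError("movement step needs class labels")
    labeled = np.flatnonzero(latent_labels != UNLABELED)
    if labeled.size == 0:
        raise ConfigurationError("movement step needs at least one labeled latent point")

    R = responsibilities(model, data.X)  # (N, K)
    T_data = model._prepare(data.X)      # model (post-PCA) space
    Y = model.manifold()
    targets = Y.copy()

    any_contrib = False
    for k in labeled:
        mask = R[:, k] > rr
        if not mask.any():
            continue
        any_contrib = True
        signs = np.where(data.y[mask] == latent_labels[k], 1.0, -1.0)
        disp = (signs[:, None] * (T_data[mask] - Y[k])).sum(axis=0)
        n_div = int(mask.sum()) if n_convention == "contributors" else data.n
        targets[k] = Y[k] + disp / n_div

    if not any_contrib:
        warnings.warn(
            "no compound exceeds the responsibility radius for any labeled "
            "latent point; model returned unchanged"
        )
        return model

    Phi = model.phi()
    reg = max(model.ridge, 1e-8) * np.eye(Phi.shape[1])
    reg[-1, -1] = 0.0
    W_new = np.linalg.solve(Phi.T @ Phi + reg, Phi.T @ targets)
    return replace(model, W=W_new, ll_trace=list(model.ll_trace))


def fit_sgtm(
    data: LabeledDataset,
    thr: float = 0.05,
    rho: float = 40.0,
    rr: float = 0.01,
    n_iters: int = 20,
    seed: int = 0,
    n_convention: str = "contributors",
    **gtm_params,
) -> SGTMModel:
    """Train a supervised GTM: converged unsupervised fit, then ``n_iters``
    alternations of latent labeling and manifold movement.

    Stops early when the latent labels are unchanged and W moved by less
    than 1e-6.  A warning suggests lowering ``thr`` (or adjusting ``rho``,
    useful for imbalanced data) if no node gets labeled on iteration 1.
    """
    if data.y is None or len(np.unique(data.y)) != 2:
        raise ConfigurationError("supervised GTM needs two classes")
    model = fit_gtm(data.X, seed=seed, **gtm_params)

    labels = np.full(model.K, UNLABELED, dtype=int)
    done = 0
    for it in range(n_iters):
        new_labels = label_latent_points(model, data, thr, rho, prev_labels=labels)
        if it == 0 and np.all(new_labels == UNLABELED):
            warnings.warn(
                "no latent point labeled on iteration 1; consider lowering thr "
                "or adjusting rho (useful for imbalanced data)"
            )
        if np.all(new_labels == UNLABELED):
            labels = new_labels
            done = it + 1
            break
        moved = movement_step(model, data, new_labels, rr, n_convention=n_convention)
        delta_w = float(np.abs(moved.W - model.W).max())
        converged = np.array_equal(new_labels, labels) and delta_w < 1e-6
        model, labels = moved, new_labels
        done = it + 1
        if converged:
            break

    return SGTMModel(
        base=model,
        latent_labels=labels,
        thr=thr,
        rho=rho,
        rr=rr,
        n_supervised_iters=done,
    )


def project_sgtm(
    model: SGTMModel,
    T: np.ndarray,
    mode: str = "mean",
    ids: list[str] | None = None,
) -> Projection2D:
    """Map compounds with the moved manifold.

    Identical algorithm to :func:`chemography.gtm.project`; label
    information of ``T`` is never used, so training compounds land exactly
    on their training positions.
    """
    return project(model.base, T, mode=mode, ids=ids, method_tag="sgtm")
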