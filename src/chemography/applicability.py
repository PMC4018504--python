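"""Applicability-domain scoring: the Ball and the Local Outlier Factor.

Both methods rank compounds by "outlierness" so that predictions can be
restricted to the region of descriptor space the training data actually
covers.

*Ball* fits a weighted L^p ball around the data: with the centroid a
fixed, it finds the simplex weight vector w (w_j >= 0, sum w_j = 1)
minimizing the radius rho such that sum_j w_j |x_ij - a_j|^p <= rho for
the covered compounds.  Because a is fixed, the objective is linear in w
for every p, so a single linear program solves the fit exactly.  A
compound's outlierness is its weighted deviation sum_j w_j |x_ij - a_j|^p.

*LOF* compares local densities.  dist_k(p) is the k-distance, N_k(p) the
(possibly tie-enlarged) k-neighborhood, rdist_k(p,o) = max(dist_k(o),
d(p,o)) the reachability distance, and

    lrd_k(p)  = ( sum_{o in N_k(p)} rdist_k(p,o) / |N_k(p)| )^-1
    LOF_k(p)  =   sum_{o in N_k(p)} lrd_k(o) / lrd_k(p) / |N_k(p)|.

LOF ~ 1 deep inside a cluster and grows for isolated compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import pdist, squareform

_LRD_CAP = 1e12


@dataclass
class BallModel:
    """Weighted L^p ball: simplex weights w, centroid a, order p, radius."""

    w: np.ndarray
    a: np.ndarray
    p: float
    radius: float

    def __post_init__(self) -> None:
        if np.any(self.w < -1e-12) or abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must lie on the probability simplex")


@dataclass
class LOFResult:
    """Per-compound LOF diagnostics."""

    k: int
    dist_k: np.ndarray
    n_neighbors: np.ndarray
    lrd: np.ndarray
    lof: np.ndarray
    capped: np.ndarray  # compounds whose lrd hit the duplicate-point cap


def _deviations(X: np.ndarray, a: np.ndarray, p: float) -> np.ndarray:
    return np.abs(np.asarray(X, dtype=float) - a) ** p


def fit_ball(X: np.ndarray, p: float = 2.0, coverage: float = 1.0) -> BallModel:
    """Fit the minimal weighted L^p ball around the data.

    ``coverage < 1`` peels the most deviant ``(1 - coverage)`` fraction
    (scored by a full fit) and re-solves on the survivors; the default
    ``coverage = 1`` constrains every compound.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    n, d = X.shape
    a = X.mean(axis=0)
    C = _deviations(X, a, p)

    def solve(C_sub: np.ndarray) -> tuple[np.ndarray, float]:
        if C_sub.size == 0 or np.allclose(C_sub, 0.0):
            return np.full(d, 1.0 / d), 0.0
        # vars: [w_1..w_d, rho];  min rho  s.t.  C w - rho <= 0, sum w = 1
        c_obj = np.zeros(d + 1)
        c_obj[-1] = 1.0
        A_ub = np.column_stack([C_sub, -np.ones(len(C_sub))])
        A_eq = np.concatenate([np.ones(d), [0.0]])[None, :]
        res = linprog(
            c_obj, A_ub=A_ub, b_ub=np.zeros(len(C_sub)),
            A_eq=A_eq, b_eq=[1.0],
            bounds=[(0, None)] * d + [(0, None)],
            method="highs",
        )
        if not res.success:
            raise RuntimeError(f"ball LP failed: {res.message}")
        w = np.clip(res.x[:d], 0.0, None)
        w /= w.sum()
        return w, float(res.x[-1])

    w, radius = solve(C)
    if coverage < 1.0:
        scores = C @ w
        n_keep = max(1, int(np.ceil(coverage * n)))
        keep = np.argsort(scores, kind="stable")[:n_keep]
        w, radius = solve(C[keep])
    return BallModel(w=w, a=a, p=float(p), radius=radius)


def ball_scores(model: BallModel, X: np.ndarray) -> np.ndarray:
    """Outlierness: weighted p-th-power deviation from the centroid."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.a.shape[0]:
        raise ValueError(
            f"compound has {X.shape[1]} features; ball lives in {model.a.shape[0]}-D"
        )
    return _deviations(X, model.a, model.p) @ model.w


def lof(X: np.ndarray, k: int = 10) -> LOFResult:
    """Local outlier factor of every compound (exact, with tie handling)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < N={n}")
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)

    sorted_d = np.sort(D, axis=1)
    dist_k = sorted_d[:, k - 1]
    neighborhoods = [np.flatnonzero(D[i] <= dist_k[i]) for i in range(n)]
    sizes = np.array([len(nb) for nb in neighborhoods])

    lrd = np.empty(n)
    capped = np.zeros(n, dtype=bool)
    for i, nb in enumerate(neighborhoods):
        reach = np.maximum(dist_k[nb], D[i, nb])
        mean_reach = reach.mean()
        if mean_reach <= 0:
            lrd[i] = _LRD_CAP
            capped[i] = True
        else:
            lrd[i] = 1.0 / mean_reach
    if capped.any():
        warnings.warn(f"{int(capped.sum())} compound(s) with duplicate neighbors; lrd capped")

    lof_vals = np.array(
        [lrd[nb].mean() / lrd[i] for i, nb in enumerate(neighborhoods)]
    )
    return LOFResult(k=k, dist_k=dist_k, n_neighbors=sizes, lrd=lrd,
                     lof=lof_vals, capped=capped)


def reachability_distance(dist_k_o: float, d_po: float) -> float:
    """rdist_k(p, o) = max(dist_k(o), d(p, o))."""
    return max(dist_k_o, d_po)


def ad_curve(scores: np.ndarray, evaluate, fractions, labels=None):
    """Accuracy as a function of the retained data fraction.

    ``scores`` rank compounds by outlierness (largest removed first);
    ``evaluate(indices) -> balanced accuracy`` re-scores the surviving
    subset.  Fractions leaving fewer than 2 compounds in some class are
    skipped with a warning.  Returns a list of (fraction, BA) pairs.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    order = np.argsort(-scores, kind="stable")  # most outlying first
    curve = []
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        n_keep = int(round(f * n))
        if n_keep < 1:
            warnings.warn(f"fraction {f} keeps no compounds; skipped")
            continue
        keep = np.sort(order[n - n_keep :] if n_keep < n else np.arange(n))
        if labels is not None:
            y = np.asarray(labels)[keep]
            counts = np.bincount(y, minlength=2)
            if (counts[np.unique(np.asarray(labels))] < 2).any():
                warnings.warn(f"fraction {f} leaves < 2 compounds in a class; skipped")
                continue
        curve.append((float(f), float(evaluate(keep))))
    return curve
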