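"""Independent brute-force reference implementations.

Deliberately written as plain double loops over the defining formulas,
sharing no code with the package, so they can serve as oracles.
"""

from __future__ import annotations

import math

import numpy as np


def gamma_brute(coords, labels, k):
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    n = len(coords)
    G = np.empty(n)
    for l in range(n):
        d = [(np.linalg.norm(coords[l] - coords[j]), j) for j in range(n) if j != l]
        d.sort()
        nbrs = [j for _, j in d[:k]]
        G[l] = sum(labels[j] == labels[l] for j in nbrs) / k
    gammas = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        gammas.append(sum(G[l] for l in members) / len(members))
    return sum(gammas) / len(gammas)


def dsc_brute(coords, labels):
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    classes = list(np.unique(labels))
    cents = {c: coords[labels == c].mean(axis=0) for c in classes}
    per_class = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        good = 0
        for l in members:
            dists = {cc: np.linalg.norm(coords[l] - cents[cc]) for cc in classes}
            nearest = min(dists, key=lambda cc: (dists[cc],))
            own = dists[c]
            others = [dists[cc] for cc in classes if cc != c]
            if others and own < min(others):
                good += 1
            elif not others:
                good += 1
        per_class.append(good / len(members))
    return sum(per_class) / len(per_class)


def dc_brute(coords, labels, grid=(15, 15)):
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    classes = list(np.unique(labels))
    if len(classes) == 1:
        return 1.0
    rows, cols = grid

    def bin_index(v, lo, hi, nb):
        if hi <= lo:
            return 0
        s = (v - lo) / (hi - lo) * nb
        i = math.ceil(s) - 1
        return min(max(i, 0), nb - 1)

    xlo, xhi = coords[:, 0].min(), coords[:, 0].max()
    ylo, yhi = coords[:, 1].min(), coords[:, 1].max()
    regions = {}
    for i in range(len(coords)):
        key = (bin_index(coords[i, 1], ylo, yhi, rows),
               bin_index(coords[i, 0], xlo, xhi, cols))
        regions.setdefault(key, []).append(labels[i])
    total = 0.0
    for labs in regions.values():
        p_R = len(labs)
        H = 0.0
        for c in classes:
            p = labs.count(c) / p_R
            if p > 0:
                H -= p * math.log2(p)
        total += p_R * H
    Z = len(coords) * math.log2(len(classes))
    return 1.0 - total / Z


def lof_brute(X, k):
    X = np.asarray(X, float)
    n = len(X)
    D = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(n)] for i in range(n)])
    dist_k = np.empty(n)
    nbrs = []
    for p in range(n):
        others = sorted(D[p, o] for o in range(n) if o != p)
        dist_k[p] = others[k - 1]
        nbrs.append([o for o in range(n) if o != p and D[p, o] <= dist_k[p]])
    lrd = np.empty(n)
    for p in range(n):
        reach = [max(dist_k[o], D[p, o]) for o in nbrs[p]]
        mean_reach = sum(reach) / len(reach)
        lrd[p] = 1e12 if mean_reach == 0 else 1.0 / mean_reach
    out = np.empty(n)
    for p in range(n):
        out[p] = sum(lrd[o] for o in nbrs[p]) / (len(nbrs[p]) * lrd[p])
    return out


def ball_objective_brute(X, p, n_grid=400):
    """Min over a simplex grid (2-D feature space only) of the max weighted deviation."""
    X = np.asarray(X, float)
    assert X.shape[1] == 2
    a = X.mean(axis=0)
    C = np.abs(X - a) ** p
    best = np.inf
    for w1 in np.linspace(0.0, 1.0, n_grid + 1):
        w = np.array([w1, 1.0 - w1])
        best = min(best, float((C @ w).max()))
    return best


def ba_brute(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = sum(1 for t, q in zip(y_true, y_pred) if t == 1 and q == 1)
    fn = sum(1 for t, q in zip(y_true, y_pred) if t == 1 and q != 1)
    tn = sum(1 for t, q in zip(y_true, y_pred) if t == 0 and q != 1)
    fp = sum(1 for t, q in zip(y_true, y_pred) if t == 0 and q == 1)
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def alert_fractions_brute(X, pred):
    X = np.asarray(X)
    pred = np.asarray(pred)
    n_act = int((pred == 1).sum())
    n_inact = int((pred == 0).sum())
    fr_act, fr_inact = [], []
    for j in range(X.shape[1]):
        fr_act.append(sum(X[i, j] for i in range(len(X)) if pred[i] == 1) / n_act)
        fr_inact.append(sum(X[i, j] for i in range(len(X)) if pred[i] == 0) / n_inact)
    return np.array(fr_act), np.array(fr_inact)
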