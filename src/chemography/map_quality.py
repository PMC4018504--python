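"""Map-quality statistics: Gamma-score, Distance Consistency, Distribution
Consistency.

All three score a 2-D map of labeled compounds on [0, 1]:

* Gamma-score -- neighborhood purity.  For each projection the fraction
  G(l, k) of its k nearest map neighbors sharing its class is averaged
  within each class (gamma_i) and then across classes.
* Distance Consistency (DSC) -- centroid consistency.  A compound counts
  as consistent iff its own class centroid is strictly the nearest class
  centroid; per-class means are averaged across classes.  DSC = 1 when
  the map shows one separate cluster per class.
* Distribution Consistency (DC) -- region purity.  The map bounding box is
  cut into an equal-rectangle grid (default 15 x 15); each occupied region
  R contributes its Shannon entropy H(R) over within-region class
  proportions, weighted by its occupancy p_R, and
  DC = 1 - (1/Z) sum_R p_R H(R) with Z = n log2(n_classes).

Note the class-mean-of-means structure of Gamma and DSC: every class has
equal say regardless of size, which is what makes the scores informative
on the heavily imbalanced datasets common in liability modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import Projection2D


@dataclass
class QualityReport:
    """Gamma/DSC/DC for one 2-D map against class labels."""

    gamma: float
    dsc: float
    dc: float
    k_used: int
    grid_used: tuple[int, int]

    def as_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "dsc": self.dsc,
            "dc": self.dc,
            "k": self.k_used,
            "grid": list(self.grid_used),
        }


def _coords_labels(proj, labels):
    coords = proj.coords if isinstance(proj, Projection2D) else np.atleast_2d(proj)
    labels = np.asarray(labels)
    if len(labels) != len(coords):
        raise ValueError("labels do not align with projections")
    return np.asarray(coords, dtype=float), labels


def gamma_score(proj, labels, k: int = 5) -> float:
    """Same-class fraction among each projection's k nearest map neighbors,
    averaged per class and then over classes."""
    coords, labels = _coords_labels(proj, labels)
    n = len(coords)
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < N={n}")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts <= k).any():
        warnings.warn("a class has <= k members; some neighbors are forced cross-class")

    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    # ties broken by compound index (stable lexsort)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), D), axis=1)
    nbrs = order[:, :k]
    G = (labels[nbrs] == labels[:, None]).mean(axis=1)
    gammas = [G[labels == c].mean() for c in classes]
    return float(np.mean(gammas))


def distance_consistency(proj, labels) -> float:
    """Fraction of compounds strictly nearest their own class centroid
    (class-averaged).  Exact centroid ties count as inconsistent."""
    coords, labels = _coords_labels(proj, labels)
    classes = np.unique(labels)
    if len(classes) == 1:
        return 1.0
    centroids = np.vstack([coords[labels == c].mean(axis=0) for c in classes])
    dist = cdist(coords, centroids)
    own = np.searchsorted(classes, labels)
    own_dist = dist[np.arange(len(coords)), own]
    other = dist.copy()
    other[np.arange(len(coords)), own] = np.inf
    consistent = own_dist < other.min(axis=1)
    per_class = [consistent[labels == c].mean() for c in classes]
    return float(np.mean(per_class))


def region_entropy(class_counts) -> float:
    """Shannon entropy (bits) of the class mix inside one map region.

    0 when all points share one label; log2(n_classes) at an equal mix.
    """
    counts = np.asarray(class_counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 normalizes -0.0


def _region_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Half-open binning with boundary points assigned to the lower region."""
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(len(values), dtype=int)
    scaled = (values - lo) / (hi - lo) * n_bins
    idx = np.ceil(scaled).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def distribution_consistency(proj, labels, grid: tuple[int, int] = (15, 15)) -> float:
    """Entropy-based region purity over an equal-rectangle partition of the map."""
    coords, labels = _coords_labels(proj, labels)
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1 x 1")
    classes = np.unique(labels)
    n_classes = len(classes)
    if n_classes == 1:
        return 1.0

    ix = _region_indices(coords[:, 0], cols)
    iy = _region_indices(coords[:, 1], rows)
    region = iy * cols + ix
    class_idx = np.searchsorted(classes, labels)

    n = len(coords)
    weighted = 0.0
    for r in np.unique(region):
        counts = np.bincount(class_idx[region == r], minlength=n_classes)
        weighted += counts.sum() * region_entropy(counts)
    Z = n * np.log2(n_classes)
    return float(1.0 - weighted / Z)


def quality_report(proj, labels, k: int = 5, grid: tuple[int, int] = (15, 15)) -> QualityReport:
    """All three statistics for one map."""
    return QualityReport(
        gamma=gamma_score(proj, labels, k=k),
        dsc=distance_consistency(proj, labels),
        dc=distribution_consistency(proj, labels, grid=grid),
        k_used=k,
        grid_used=tuple(grid),
    )
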