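"""Balanced accuracy, stratified external cross-validation, grid search.

Balanced Accuracy BA = (Sens + Spec)/2 = (tp/(tp+fn) + tn/(tn+fp))/2
compensates class imbalance: a constant single-class predictor scores 0.5
however skewed the data.

Cross-validation is *external*: every preprocessing step (scaling, PCA)
must be fitted inside each training fold, which is why the harness takes a
model *factory* -- a zero-argument callable returning a fresh
fit/predict object -- rather than a fitted model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import ConfigurationError, LabeledDataset


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred, positive: int = 1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    return ConfusionCounts(
        tp=int(np.sum(pos & (y_pred == positive))),
        tn=int(np.sum(~pos & (y_pred != positive))),
        fp=int(np.sum(~pos & (y_pred == positive))),
        fn=int(np.sum(pos & (y_pred != positive))),
    )


def balanced_accuracy(c: ConfusionCounts) -> float:
    """BA = (Sensitivity + Specificity) / 2."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ConfigurationError(
            "balanced accuracy undefined: a class is absent from the evaluation"
        )
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return 0.5 * (sens + spec)


def balanced_accuracy_score(y_true, y_pred) -> float:
    return balanced_accuracy(confusion(y_true, y_pred))


@dataclass
class CVResult:
    fold_ba: list[float]
    mean_ba: float
    predictions: np.ndarray
    fold_assignment: np.ndarray


def cross_validate(
    data: LabeledDataset,
    model_factory,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified n-fold external CV; every compound predicted exactly once
    by a model that never saw it.  Deterministic given ``seed``."""
    if data.y is None:
        raise ConfigurationError("cross-validation needs labels")
    counts = data.class_counts()
    if min(counts.values()) < n_folds:
        raise ConfigurationError(
            f"smallest class ({min(counts.values())}) cannot be stratified into {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    predictions = np.full(data.n, -1, dtype=int)
    assignment = np.full(data.n, -1, dtype=int)
    fold_ba = []
    for fold, (tr, te) in enumerate(skf.split(data.X, data.y)):
        model = model_factory()
        model.fit(data.X[tr], data.y[tr])
        pred = np.asarray(model.predict(data.X[te]))
        predictions[te] = pred
        assignment[te] = fold
        fold_ba.append(balanced_accuracy_score(data.y[te], pred))
    return CVResult(
        fold_ba=fold_ba,
        mean_ba=float(np.mean(fold_ba)),
        predictions=predictions,
        fold_assignment=assignment,
    )


@dataclass
class GridSearchResult:
    best_params: dict
    best_ba: float
    leaderboard: list = field(default_factory=list)  # (params, mean_ba) pairs


def grid_search(
    data: LabeledDataset,
    model_factory,
    param_grid: dict,
    n_folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive sweep: each grid point is scored by cross-validated mean BA.

    ``model_factory(**params)`` builds the candidate.  Grid points are
    visited in the given order and only a strictly better BA replaces the
    incumbent, so listing parameter values from simple to complex breaks
    ties toward the smaller model (the shipped presets are ordered so).
    """
    keys = list(param_grid)
    if not keys or any(len(param_grid[k]) == 0 for k in keys):
        raise ConfigurationError("parameter grid is empty")
    best, best_ba, leaderboard = None, -np.inf, []
    for values in itertools.product(*(param_grid[k] for k in keys)):
        params = dict(zip(keys, values))
        result = cross_validate(data, lambda: model_factory(**params),
                                n_folds=n_folds, seed=seed)
        leaderboard.append((params, result.mean_ba))
        if result.mean_ba > best_ba:
            best, best_ba = params, result.mean_ba
    return GridSearchResult(best_params=best, best_ba=float(best_ba),
                            leaderboard=leaderboard)


#: Published tuning grids for each method, ordered simple -> complex for tie-breaking.
PRESET_GRIDS = {
    "svm": {
        "nu": [round(v, 2) for v in np.arange(0.01, 0.92, 0.10)],
        "gamma": [2.0**e for e in range(-11, 4)],
    },
    "gtm": {
        "K": [s**2 for s in range(5, 51, 5)],
        "M": [s**2 for s in range(2, 8)],
        "pca_components": list(range(20, 61, 10)),
    },
    "pnn": {"sigma": [round(s, 2) for s in np.linspace(0.05, 1.0, 20)]},
    "sgtm": {
        "thr": [round(t, 3) for t in np.linspace(0.0, 0.2, 9)],
        "rho": [30.0, 40.0],
    },
}
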