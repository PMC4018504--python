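"""Core domain types and table I/O.

The universal input is a :class:`LabeledDataset`: a descriptor matrix
(compounds x features) with per-compound identifiers and, optionally, a
binary activity label.  Descriptor tables arrive as delimited text with a
header row; structure handling (SMILES/SDF) lives in the optional
:mod:`chemography.structures` adapter and is never required here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


class ConfigurationError(ValueError):
    """A parameter or column specification is invalid."""


class ParseError(ValueError):
    """A cell in the input table could not be interpreted."""


@dataclass
class LabeledDataset:
    """Descriptor matrix with aligned compound ids and optional binary labels.

    Attributes
    ----------
    ids : list of str
        Compound identifiers, one per row of ``X``.
    X : ndarray, shape (n_compounds, n_features)
        Real-valued descriptor matrix (unitless).
    y : ndarray of int in {0, 1}, or None
        Per-compound class label; ``None`` for unlabeled sets.
    feature_names : list of str
        One name per column of ``X``.
    meta : dict
        Free-form provenance (generator parameters, label mapping, ...).
    """

    ids: list[str]
    X: np.ndarray
    y: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ConfigurationError("X must be a 2-D matrix")
        n, d = self.X.shape
        if n < 1 or d < 1:
            raise ConfigurationError("dataset needs at least one row and one column")
        if len(self.ids) != n:
            raise ConfigurationError("ids do not align with rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ParseError("descriptor matrix contains missing or non-finite values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape != (n,):
                raise ConfigurationError("y does not align with rows of X")
            if not np.isin(self.y, (0, 1)).all():
                raise ConfigurationError("labels must be encoded in {0, 1}")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(d)]
        elif len(self.feature_names) != d:
            raise ConfigurationError("feature_names do not align with columns of X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[int, int]:
        if self.y is None:
            raise ConfigurationError("dataset is unlabeled")
        classes, counts = np.unique(self.y, return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            feature_names=list(self.feature_names),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame.insert(0, "id", self.ids)
        if self.y is not None:
            frame["class"] = self.y
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Projection2D:
    """2-D map coordinates for a set of compounds (relative units)."""

    ids: list[str]
    coords: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ConfigurationError("coords must be an N x 2 matrix")
        if len(self.ids) != self.coords.shape[0]:
            raise ConfigurationError("ids do not align with coords")
        if not np.all(np.isfinite(self.coords)):
            raise ConfigurationError("map coordinates must be finite")


@dataclass
class PCATransform:
    """Orthonormal linear projection fitted by principal component analysis."""

    mean: np.ndarray
    components: np.ndarray  # (D, d_pca), columns orthonormal
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.components

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z @ self.components.T + self.mean


def fit_pca(data, n_components: int) -> PCATransform:
    """Fit a PCA pre-transform with components ordered by explained variance.

    ``data`` may be a :class:`LabeledDataset` or a plain matrix.  Requires
    ``1 <= n_components <= min(N - 1, D)``.
    """
    X = data.X if isinstance(data, LabeledDataset) else np.asarray(data, dtype=float)
    n, d = X.shape
    hi = min(n - 1, d)
    if not 1 <= n_components <= hi:
        raise ConfigurationError(
            f"n_components={n_components} outside valid range [1, {hi}] for data of shape {X.shape}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return PCATransform(
        mean=pca.mean_.copy(),
        components=pca.components_.T.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )


@dataclass
class Standardizer:
    """Column-wise zero-mean / unit-variance scaling (constant columns untouched)."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=X.mean(axis=0), scale=scale)


def load_dataset(
    path,
    label_column: str | None = "class",
    id_column: str | None = "id",
    *,
    sep: str | None = None,
    drop_constant: bool = True,
    variance_eps: float = 1e-8,
    label_map: Mapping[str, int] | None = None,
    impute: bool = False,
) -> LabeledDataset:
    """Read a delimited descriptor table into a :class:`LabeledDataset`.

    Parameters
    ----------
    label_column, id_column
        Header names; ``label_column=None`` loads an unlabeled set.
    sep
        Field separator; inferred from the file when omitted.
    drop_constant
        Remove constant and nearly constant descriptor columns
        (column variance below ``variance_eps``).
    label_map
        Explicit label-string -> {0,1} mapping.  By default the
        lexicographically first label string maps to class 0.
    impute
        Replace missing numeric cells by the column mean instead of
        rejecting the file.
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if id_column is not None and id_column not in frame.columns:
        raise ConfigurationError(f"id column {id_column!r} not found in {path}")
    if label_column is not None and label_column not in frame.columns:
        raise ConfigurationError(f"label column {label_column!r} not found in {path}")

    ids = (
        frame[id_column].astype(str).tolist()
        if id_column is not None
        else [str(i) for i in range(len(frame))]
    )
    feature_cols = [c for c in frame.columns if c not in (id_column, label_column)]
    if not feature_cols:
        raise ConfigurationError("no feature columns in table")

    X = np.empty((len(frame), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        raw = frame[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
            raise ParseError(f"non-numeric value at row {row}, col {col}")
        X[:, j] = numeric.to_numpy(dtype=float)

    if np.isnan(X).any():
        if not impute:
            rows, cols = np.nonzero(np.isnan(X))
            raise ParseError(
                f"missing value at row {rows[0] + 1}, col {feature_cols[cols[0]]}"
                " (pass impute=True to mean-impute)"
            )
        col_means = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(col_means, inds[1])

    names = list(feature_cols)
    if drop_constant:
        keep = X.var(axis=0) >= variance_eps
        if not keep.any():
            raise ConfigurationError("all descriptor columns are (nearly) constant")
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]

    y = None
    if label_column is not None:
        raw_labels = frame[label_column]
        if label_map is None:
            uniq = sorted(raw_labels.astype(str).unique())
            if len(uniq) > 2:
                raise ConfigurationError(
                    f"expected at most two classes, found {len(uniq)}: {uniq}"
                )
            label_map = {lab: i for i, lab in enumerate(uniq)}
        y = raw_labels.astype(str).map(label_map).to_numpy()
        if pd.isna(y).any():
            missing = sorted(set(raw_labels.astype(str)) - set(label_map))
            raise ConfigurationError(f"labels without mapping: {missing}")
        y = y.astype(int)

    return LabeledDataset(
        ids=ids,
        X=X,
        y=y,
        feature_names=names,
        meta={"source": str(path), "label_map": dict(label_map) if label_map else None},
    )
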