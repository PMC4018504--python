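"""Classifiers: probabilistic neural network plus a pluggable adapter layer.

The PNN is a Parzen-window kernel classifier laid out as four layers.  The
input layer presents a compound vector; every training compound owns one
pattern unit whose weight vector is its (unit-normalized) descriptor
vector; a pattern unit forms the dot product Z with the input and fires
exp((Z - 1)/sigma^2); the summation layer adds the activations per class;
the output layer picks the class of the largest sum.  There is no
iterative training -- fitting stores the patterns.

The adapter layer lets any external classifier with fit/predict (e.g. an
SVM from scikit-learn) enter the same cross-validation harness; SVM
internals are deliberately not re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ConfigurationError, LabeledDataset, Standardizer


def _unit_rows(X: np.ndarray, what: str) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ConfigurationError(f"zero-vector {what} cannot be unit-normalized")
    return X / norms[:, None]


@dataclass
class PNNModel:
    """Stored pattern layer: unit-normalized training vectors with labels."""

    pattern_vectors: np.ndarray
    pattern_labels: np.ndarray
    sigma: float
    classes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.classes.size == 0:
            self.classes = np.unique(self.pattern_labels)


def fit_pnn(X: np.ndarray, y: np.ndarray, sigma: float = 0.2) -> PNNModel:
    """'Train' a PNN by storing unit-normalized patterns."""
    return PNNModel(
        pattern_vectors=_unit_rows(X, "pattern"),
        pattern_labels=np.asarray(y, dtype=int),
        sigma=float(sigma),
    )


def pnn_predict(model: PNNModel, T: np.ndarray):
    """Class scores and argmax prediction for each compound.

    Per class, score = sum over that class's pattern units of
    exp((Z - 1)/sigma^2) with Z the input/pattern dot product.  Scores are
    normalized to probability-like outputs summing to 1.
    """
    Tn = _unit_rows(T, "input")
    Z = Tn @ model.pattern_vectors.T
    act = np.exp((Z - 1.0) / model.sigma**2)
    scores = np.column_stack(
        [act[:, model.pattern_labels == c].sum(axis=1) for c in model.classes]
    )
    probs = scores / scores.sum(axis=1, keepdims=True)
    predicted = model.classes[np.argmax(probs, axis=1)]
    return probs, predicted


class PNNClassifier:
    """fit/predict adapter around the PNN for the evaluation harness."""

    def __init__(self, sigma: float = 0.2):
        self.sigma = sigma
        self.model: PNNModel | None = None

    def fit(self, X, y):
        self.model = fit_pnn(X, y, sigma=self.sigma)
        return self

    def predict(self, X):
        _, pred = pnn_predict(self.model, X)
        return pred

    def scores(self, X):
        probs, _ = pnn_predict(self.model, X)
        return probs


class GTMBayesClassifier:
    """Per-class GTM densities + Bayes posterior, harness-compatible.

    Standardization and the optional PCA are fitted inside ``fit`` only,
    so cross-validation never leaks test-fold statistics.
    """

    def __init__(self, K: int = 16, M: int = 4, pca_components: int | None = None,
                 standardize: bool = True, seed: int = 0, **gtm_params):
        self.K, self.M = K, M
        self.pca_components = pca_components
        self.standardize = standardize
        self.seed = seed
        self.gtm_params = gtm_params
        self.model = None
        self._scaler: Standardizer | None = None

    def fit(self, X, y):
        from .gtm import fit_class_density

        X = np.asarray(X, dtype=float)
        if self.standardize:
            self._scaler = Standardizer.fit(X)
            X = self._scaler.transform(X)
        data = LabeledDataset(
            ids=[str(i) for i in range(len(X))], X=X, y=np.asarray(y, dtype=int)
        )
        self.model = fit_class_density(
            data, pca_components=self.pca_components,
            K=self.K, M=self.M, seed=self.seed, **self.gtm_params,
        )
        return self

    def _transform(self, X):
        X = np.asarray(X, dtype=float)
        return self._scaler.transform(X) if self._scaler is not None else X

    def predict(self, X):
        from .gtm import classify

        _, pred, _ = classify(self.model, self._transform(X))
        return pred

    def scores(self, X):
        from .gtm import classify

        probs, _, _ = classify(self.model, self._transform(X))
        return probs


class SklearnClassifier:
    """Adapter wrapping any scikit-learn style estimator factory.

    Example: ``SklearnClassifier(lambda: NuSVC(nu=0.5, gamma=2**-3))``
    plugs an SVM into cross-validation without re-implementing it.
    """

    def __init__(self, factory):
        self.factory = factory
        self.estimator = None

    def fit(self, X, y):
        self.estimator = self.factory()
        self.estimator.fit(X, y)
        return self

    def predict(self, X):
        return self.estimator.predict(X)

    def scores(self, X):
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)
        return self.estimator.decision_function(X)
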