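"""Seeded synthetic fixtures with the statistical structure of liability data.

Every generator is fully deterministic given its seed (NumPy PCG64 via
``default_rng``), records its parameters in the dataset's ``meta``, and
emits the same CSV dialect the loader reads, so CLI round-trips need no
special casing.  The generators emulate, in order: labeled Gaussian class
clusters (optionally imbalanced up to the 17:1 regime real acute-toxicity
data shows), labeled low-dimensional manifolds embedded in high dimension,
Bernoulli fragment-occurrence matrices with class-enriched fragments, and
clusters with planted mislabeled fringe compounds for applicability-domain
studies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .data import ConfigurationError, LabeledDataset


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    generator: str
    n_per_class: tuple[int, int] = (100, 100)
    dim: int = 10
    noise: float = 1.0
    separation: float = 4.0
    seed: int = 0

    def generate(self) -> LabeledDataset:
        fn = {
            "gaussian": lambda: gaussian_classes(
                n_per_class=self.n_per_class, dim=self.dim,
                separation=self.separation, noise=self.noise, seed=self.seed),
            "swiss_roll": lambda: labeled_swiss_roll(
                n=sum(self.n_per_class), noise=self.noise, seed=self.seed),
            "fragments": lambda: fragment_matrix(
                n_per_class=self.n_per_class, seed=self.seed),
            "noisy_fringe": lambda: noisy_fringe(
                n_per_class=self.n_per_class, dim=self.dim,
                separation=self.separation, seed=self.seed),
        }.get(self.generator)
        if fn is None:
            raise ConfigurationError(f"unknown generator {self.generator!r}")
        return fn()


def _ids(n: int, prefix: str = "c") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def gaussian_classes(
    n_per_class: tuple[int, int] = (100, 100),
    dim: int = 10,
    separation: float = 4.0,
    noise: float = 1.0,
    noise_kind: str = "gaussian",
    seed: int = 0,
) -> LabeledDataset:
    """Two spherical class blobs at centroid distance ``separation``.

    ``n_per_class`` controls imbalance, e.g. (578, 34) reproduces the
    17:1 active/inactive skew of real acute-toxicity collections.
    ``noise_kind="ball"`` draws each blob uniformly from a ball of radius
    ``noise``, so ``separation > 2 * noise`` guarantees strictly
    (linearly) separable classes.
    """
    n0, n1 = n_per_class
    if min(n0, n1) < 2:
        raise ConfigurationError("need at least 2 compounds per class")
    if separation < 0:
        raise ConfigurationError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    offset = np.zeros(dim)
    offset[0] = separation

    def blob(n: int) -> np.ndarray:
        if noise_kind == "gaussian":
            return rng.standard_normal((n, dim)) * noise
        if noise_kind == "ball":
            g = rng.standard_normal((n, dim))
            g /= np.linalg.norm(g, axis=1)[:, None]
            radii = noise * rng.random(n) ** (1.0 / dim)
            return g * radii[:, None]
        raise ConfigurationError(f"unknown noise_kind {noise_kind!r}")

    X0 = blob(n0)
    X1 = blob(n1) + offset
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return LabeledDataset(
        ids=_ids(n0 + n1), X=X, y=y,
        meta={"generator": "gaussian", "n_per_class": [n0, n1], "dim": dim,
              "separation": separation, "noise": noise, "seed": seed},
    )


def labeled_swiss_roll(
    n: int = 400,
    noise: float = 0.05,
    n_bands: int = 2,
    lift_dim: int | None = None,
    seed: int = 0,
):
    """3-D swiss roll with class labels striped along the unrolled coordinate.

    Returns ``(dataset, unrolled)`` where ``unrolled`` holds the
    ground-truth (arc-length, height) coordinates for recovery tests.
    Bands adjacent in 3-D across the roll gap are distant along the
    manifold, which is exactly the structure geodesic embeddings must
    recover.  ``lift_dim`` embeds the roll in a higher dimension through a
    seeded random rotation.
    """
    if n < 50:
        raise ConfigurationError("swiss roll needs n >= 50")
    rng = np.random.default_rng(seed)
    t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, size=n)
    h = rng.uniform(0.0, 12.0, size=n)
    X = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    X += rng.standard_normal(X.shape) * noise
    # arc length of the Archimedean spiral as the unrolled coordinate
    arc = 0.5 * (t * np.sqrt(1 + t**2) + np.arcsinh(t))
    band = np.floor(
        (t - t.min()) / (t.max() - t.min() + 1e-12) * n_bands
    ).astype(int)
    band = np.minimum(band, n_bands - 1)
    y = band % 2
    if lift_dim is not None:
        if lift_dim < 3:
            raise ConfigurationError("lift_dim must be >= 3")
        Q = np.linalg.qr(rng.standard_normal((lift_dim, lift_dim)))[0]
        X = X @ Q[:3, :]
    data = LabeledDataset(
        ids=_ids(n), X=X, y=y,
        meta={"generator": "swiss_roll", "n": n, "noise": noise,
              "n_bands": n_bands, "seed": seed},
    )
    return data, np.column_stack([arc, h])


def fragment_matrix(
    n_per_class: tuple[int, int] = (250, 250),
    n_background: int = 48,
    p_background: float = 0.3,
    planted: tuple[tuple[float, float], ...] = ((0.6, 0.05),),
    seed: int = 0,
) -> LabeledDataset:
    """Bernoulli fragment-occurrence matrix with planted enriched fragments.

    ``planted`` lists (p_active, p_inactive) occurrence probabilities; the
    planted fragments occupy the first columns, named ``planted_*``.
    Background fragments occur with ``p_background`` in both classes.
    """
    n_act, n_inact = n_per_class
    probs = list(planted) + [(p_background, p_background)] * n_background
    for p_a, p_i in probs:
        if not (0.0 <= p_a <= 1.0 and 0.0 <= p_i <= 1.0):
            raise ConfigurationError("occurrence probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cols = []
    for p_a, p_i in probs:
        col = np.concatenate([
            rng.random(n_act) < p_a,
            rng.random(n_inact) < p_i,
        ])
        cols.append(col.astype(float))
    X = np.column_stack(cols)
    y = np.concatenate([np.ones(n_act, dtype=int), np.zeros(n_inact, dtype=int)])
    names = [f"planted_{j}" for j in range(len(planted))] + [
        f"bg_{j}" for j in range(n_background)
    ]
    return LabeledDataset(
        ids=_ids(n_act + n_inact), X=X, y=y, feature_names=names,
        meta={"generator": "fragments", "n_per_class": [n_act, n_inact],
              "planted": [list(p) for p in planted],
              "p_background": p_background, "seed": seed},
    )


def noisy_fringe(
    n_per_class: tuple[int, int] = (200, 200),
    dim: int = 5,
    separation: float = 6.0,
    n_outliers: int = 20,
    outlier_scale: float = 8.0,
    seed: int = 0,
) -> LabeledDataset:
    """Core class clusters plus far-flung *mislabeled* planted compounds.

    The planted compounds sit ``outlier_scale`` standard deviations from
    the data center with flipped labels, so removing them by outlierness
    raises classification accuracy -- the regime applicability-domain
    filtering is meant to exploit.  Their ids are recorded in
    ``meta["outlier_ids"]``.
    """
    core = gaussian_classes(n_per_class=n_per_class, dim=dim,
                            separation=separation, seed=seed)
    n_core = core.n
    if n_outliers >= n_core:
        raise ConfigurationError("outlier fraction must stay below 0.5")
    rng = np.random.default_rng(seed + 1)
    center = core.X.mean(axis=0)
    directions = rng.standard_normal((n_outliers, dim))
    directions /= np.linalg.norm(directions, axis=1)[:, None]
    radii = outlier_scale * (1.0 + 0.25 * rng.random(n_outliers))
    X_out = center + directions * radii[:, None]
    # mislabel: assign the class whose centroid is FARTHER
    c0 = core.X[core.y == 0].mean(axis=0)
    c1 = core.X[core.y == 1].mean(axis=0)
    d0 = np.linalg.norm(X_out - c0, axis=1)
    d1 = np.linalg.norm(X_out - c1, axis=1)
    y_out = (d0 < d1).astype(int)  # nearer class 0 -> labeled 1, and vice versa

    out_ids = [f"out{i:03d}" for i in range(n_outliers)]
    return LabeledDataset(
        ids=core.ids + out_ids,
        X=np.vstack([core.X, X_out]),
        y=np.concatenate([core.y, y_out]),
        meta={"generator": "noisy_fringe", "n_per_class": list(n_per_class),
              "dim": dim, "separation": separation, "n_outliers": n_outliers,
              "outlier_scale": outlier_scale, "seed": seed,
              "outlier_ids": out_ids},
    )
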