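"""Structural-alert mining from binary fragment descriptors.

For every fragment descriptor d, the fraction of compounds containing it
among those *predicted* active and predicted inactive is

    fr_act(d) = n_act(d) / n_act,   fr_inact(d) = n_inact(d) / n_inact.

Rare descriptors (fr_act + fr_inact < rarity_cut, default 0.05) are
excluded; the remainder are flagged as structural alerts when
fr_act / fr_inact > ratio_cut (default 2.5).  Descriptors absent from
predicted inactives but present in actives get an infinite ratio (alert
unless rarity-excluded).  Fractions are computed over predicted classes by
design -- an alert explains what the *model* keys on; a flag switches to
true labels for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AlertReport:
    """Per-descriptor occurrence statistics and alert flags."""

    descriptor_names: list[str]
    n_act: np.ndarray
    n_inact: np.ndarray
    fr_act: np.ndarray
    fr_inact: np.ndarray
    ratio: np.ndarray
    rarity_excluded: np.ndarray
    alert: np.ndarray
    rarity_cut: float
    ratio_cut: float

    def alert_names(self) -> set[str]:
        return {n for n, a in zip(self.descriptor_names, self.alert) if a}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "descriptor": self.descriptor_names,
                "n_act": self.n_act,
                "n_inact": self.n_inact,
                "fr_act": self.fr_act,
                "fr_inact": self.fr_inact,
                "ratio": self.ratio,
                "inverse_ratio": np.divide(
                    self.fr_inact, self.fr_act,
                    out=np.full_like(self.ratio, np.inf),
                    where=self.fr_act > 0,
                ),
                "rarity_excluded": self.rarity_excluded,
                "alert": self.alert,
            }
        )


def mine_alerts(
    X_binary: np.ndarray,
    predictions: np.ndarray,
    rarity_cut: float = 0.05,
    ratio_cut: float = 2.5,
    descriptor_names: list[str] | None = None,
    active_class: int = 1,
) -> AlertReport:
    """Flag fragment descriptors enriched among predicted actives."""
    X = np.asarray(X_binary)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("occurrence matrix must be binary")
    pred = np.asarray(predictions)
    if len(pred) != X.shape[0]:
        raise ValueError("predictions do not align with the occurrence matrix")
    act = pred == active_class
    n_pred_act, n_pred_inact = int(act.sum()), int((~act).sum())
    if n_pred_act == 0 or n_pred_inact == 0:
        raise ValueError("need at least one compound predicted in each class")

    n_act = X[act].sum(axis=0).astype(int)
    n_inact = X[~act].sum(axis=0).astype(int)
    fr_act = n_act / n_pred_act
    fr_inact = n_inact / n_pred_inact
    rarity = (fr_act + fr_inact) < rarity_cut

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            fr_inact > 0,
            fr_act / np.where(fr_inact > 0, fr_inact, 1.0),
            np.where(fr_act > 0, np.inf, 0.0),
        )
    inf_alerts = np.isinf(ratio) & ~rarity
    if inf_alerts.any():
        warnings.warn(
            f"{int(inf_alerts.sum())} descriptor(s) absent from predicted inactives; "
            "ratio treated as infinite"
        )
    alert = ~rarity & (ratio > ratio_cut)

    if descriptor_names is None:
        descriptor_names = [f"d{j}" for j in range(X.shape[1])]
    return AlertReport(
        descriptor_names=list(descriptor_names),
        n_act=n_act, n_inact=n_inact,
        fr_act=fr_act, fr_inact=fr_inact,
        ratio=ratio, rarity_excluded=rarity, alert=alert,
        rarity_cut=rarity_cut, ratio_cut=ratio_cut,
    )


def consensus_alerts(reports: list[AlertReport]) -> set[str]:
    """Descriptors flagged as alerts by every report (e.g. every classifier)."""
    if not reports:
        raise ValueError("need at least one report")
    universe = reports[0].descriptor_names
    for rep in reports[1:]:
        if rep.descriptor_names != universe:
            raise ValueError("reports cover different descriptor universes")
    out = reports[0].alert_names()
    for rep in reports[1:]:
        out &= rep.alert_names()
    return out
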