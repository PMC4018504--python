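"""Model persistence: one JSON file per model, versioned.

The file is a manifest (format name, version, model kind) whose payload
embeds every array as a nested list.  JSON float serialization uses
Python's shortest round-trip repr, so numeric fields survive a
save/load cycle bit-identically and reloaded models reproduce their
predictions exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .applicability import BallModel
from .classifiers import PNNModel
from .data import PCATransform
from .gtm import ClassDensityModel, GTMModel
from .isomap import IsomapModel
from .sgtm import SGTMModel

FORMAT = "chemography-model"
VERSION = 1


class ModelFormatError(ValueError):
    """File is not a readable model of a compatible version."""


def _arr(a):
    return None if a is None else np.asarray(a).tolist()


def _np(a, dtype=float):
    return None if a is None else np.asarray(a, dtype=dtype)


def _pca_payload(pca: PCATransform | None):
    if pca is None:
        return None
    return {"mean": _arr(pca.mean), "components": _arr(pca.components),
            "explained_variance": _arr(pca.explained_variance)}


def _pca_restore(payload):
    if payload is None:
        return None
    return PCATransform(mean=_np(payload["mean"]),
                        components=_np(payload["components"]),
                        explained_variance=_np(payload["explained_variance"]))


def _gtm_payload(m: GTMModel) -> dict:
    return {
        "latent_grid": _arr(m.latent_grid), "rbf_centers": _arr(m.rbf_centers),
        "rbf_width": m.rbf_width, "W": _arr(m.W), "beta": m.beta,
        "ridge": m.ridge, "ll_trace": list(m.ll_trace),
        "pca": _pca_payload(m.pca),
    }


def _gtm_restore(p: dict) -> GTMModel:
    return GTMModel(
        latent_grid=_np(p["latent_grid"]), rbf_centers=_np(p["rbf_centers"]),
        rbf_width=float(p["rbf_width"]), W=_np(p["W"]), beta=float(p["beta"]),
        ridge=float(p["ridge"]), ll_trace=list(p["ll_trace"]),
        pca=_pca_restore(p["pca"]),
    )


def _payload(model) -> tuple[str, dict]:
    if isinstance(model, SGTMModel):
        return "sgtm", {
            "base": _gtm_payload(model.base),
            "latent_labels": _arr(model.latent_labels),
            "thr": model.thr, "rho": model.rho, "rr": model.rr,
            "n_supervised_iters": model.n_supervised_iters,
        }
    if isinstance(model, GTMModel):
        return "gtm", _gtm_payload(model)
    if isinstance(model, ClassDensityModel):
        return "class_density", {
            "classes": list(map(int, model.classes)),
            "models": {str(c): _gtm_payload(model.models[c]) for c in model.classes},
            "priors": {str(c): model.priors[c] for c in model.classes},
            "pca": _pca_payload(model.pca),
        }
    if isinstance(model, IsomapModel):
        return "isomap", {
            "train_X": _arr(model.train_X), "embedding": _arr(model.embedding),
            "eigenvalues": _arr(model.eigenvalues),
            "eigenvectors": _arr(model.eigenvectors),
            "D_geo": _arr(model.D_geo), "k": model.k,
            "supervised": bool(model.supervised), "labels": _arr(model.labels),
            "alpha": model.alpha, "beta_s": model.beta_s, "beta1": model.beta1,
            "component_mask": _arr(model.component_mask),
            "dropped_ids": list(model.dropped_ids), "ids": list(model.ids),
            "scaling": model.scaling,
        }
    if isinstance(model, PNNModel):
        return "pnn", {
            "pattern_vectors": _arr(model.pattern_vectors),
            "pattern_labels": _arr(model.pattern_labels),
            "sigma": model.sigma, "classes": _arr(model.classes),
        }
    if isinstance(model, BallModel):
        return "ball", {"w": _arr(model.w), "a": _arr(model.a),
                        "p": model.p, "radius": model.radius}
    raise ModelFormatError(f"cannot serialize object of type {type(model).__name__}")


def save_model(model, path) -> None:
    kind, payload = _payload(model)
    doc = {"format": FORMAT, "version": VERSION, "kind": kind, "payload": payload}
    Path(path).write_text(json.dumps(doc))


def load_model(path):
    """Load any saved model; raises :class:`ModelFormatError` on damage or
    version mismatch rather than silently misloading."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path} is not a readable model file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT:
        raise ModelFormatError(f"{path} is not a {FORMAT} file")
    if doc.get("version") != VERSION:
        raise ModelFormatError(
            f"model version {doc.get('version')} incompatible with reader version {VERSION}"
        )
    kind, p = doc["kind"], doc["payload"]
    if kind == "gtm":
        return _gtm_restore(p)
    if kind == "sgtm":
        return SGTMModel(
            base=_gtm_restore(p["base"]),
            latent_labels=_np(p["latent_labels"], int),
            thr=float(p["thr"]), rho=float(p["rho"]), rr=float(p["rr"]),
            n_supervised_iters=int(p["n_supervised_iters"]),
        )
    if kind == "class_density":
        classes = [int(c) for c in p["classes"]]
        return ClassDensityModel(
            models={c: _gtm_restore(p["models"][str(c)]) for c in classes},
            priors={c: float(p["priors"][str(c)]) for c in classes},
            pca=_pca_restore(p["pca"]), classes=classes,
        )
    if kind == "isomap":
        return IsomapModel(
            train_X=_np(p["train_X"]), embedding=_np(p["embedding"]),
            eigenvalues=_np(p["eigenvalues"]), eigenvectors=_np(p["eigenvectors"]),
            D_geo=_np(p["D_geo"]), k=int(p["k"]),
            supervised=bool(p["supervised"]), labels=_np(p["labels"], int),
            alpha=float(p["alpha"]), beta_s=float(p["beta_s"]), beta1=float(p["beta1"]),
            component_mask=None if p["component_mask"] is None
            else np.asarray(p["component_mask"], dtype=bool),
            dropped_ids=list(p["dropped_ids"]), ids=list(p["ids"]),
            scaling=p["scaling"],
        )
    if kind == "pnn":
        return PNNModel(
            pattern_vectors=_np(p["pattern_vectors"]),
            pattern_labels=_np(p["pattern_labels"], int),
            sigma=float(p["sigma"]), classes=_np(p["classes"], int),
        )
    if kind == "ball":
        return BallModel(w=_np(p["w"]), a=_np(p["a"]),
                         p=float(p["p"]), radius=float(p["radius"]))
    raise ModelFormatError(f"unknown model kind {kind!r}")
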