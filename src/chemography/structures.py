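"""Optional structure adapter: SMILES/SDF -> binary fingerprint matrix.

A thin convenience over RDKit; the core library never requires structures
and this module imports RDKit lazily so the package works without it.
"""

from __future__ import annotations

import numpy as np

from .data import ConfigurationError, LabeledDataset


def _rdkit():
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "the structure adapter needs rdkit (pip install chemography[structures])"
        ) from exc
    return Chem, rdFingerprintGenerator


def fingerprints_from_smiles(
    smiles: list[str],
    labels=None,
    ids: list[str] | None = None,
    n_bits: int = 1024,
    radius: int = 2,
) -> LabeledDataset:
    """Morgan fingerprints as a binary LabeledDataset.

    Unparseable SMILES raise with the offending string named.
    """
    Chem, gen_mod = _rdkit()
    gen = gen_mod.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ConfigurationError(f"unparseable SMILES: {smi!r}")
        fp = gen.GetFingerprint(mol)
        rows.append(np.array(fp, dtype=float))
    X = np.vstack(rows)
    if ids is None:
        ids = [f"m{i:05d}" for i in range(len(smiles))]
    y = None if labels is None else np.asarray(labels, dtype=int)
    names = [f"bit{j}" for j in range(n_bits)]
    return LabeledDataset(ids=ids, X=X, y=y, feature_names=names,
                          meta={"adapter": "morgan", "radius": radius, "n_bits": n_bits})


def fingerprints_from_sdf(path, label_prop: str | None = None,
                          n_bits: int = 1024, radius: int = 2) -> LabeledDataset:
    """Fingerprint matrix from an SDF file; labels from a molecule property."""
    Chem, gen_mod = _rdkit()
    supplier = Chem.SDMolSupplier(str(path))
    smiles, labels, ids = [], [], []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ConfigurationError(f"unparseable molecule at SDF index {i}")
        smiles.append(Chem.MolToSmiles(mol))
        ids.append(mol.GetProp("_Name") or f"m{i:05d}")
        if label_prop is not None:
            labels.append(int(mol.GetProp(label_prop)))
    return fingerprints_from_smiles(
        smiles, labels=labels if label_prop is not None else None,
        ids=ids, n_bits=n_bits, radius=radius,
    )
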