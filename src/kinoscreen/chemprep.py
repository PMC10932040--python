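"""Structure standardization and topological fingerprints.

Every other layer of the toolkit consumes the output of this module: a
standardized canonical SMILES, a 1024-bit ECFP4 (Morgan radius-2)
fingerprint, and an average molecular weight per compound.

Standardization follows the usual curation recipe for bioactivity
modeling: keep the largest organic fragment (salts and addends dropped),
neutralize charges where chemically sensible, canonicalize tautomers,
and strip stereochemistry / E-Z geometry (circular fingerprints do not
distinguish stereoisomers, so keeping them would create duplicate rows
with identical features).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

N_BITS_DEFAULT = 1024


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the offender."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """A standardized compound with its feature representations."""

    compound_id: str
    raw_smiles: str
    canonical_smiles: str
    fingerprint: np.ndarray  # uint8, length n_bits
    mol_weight: float


_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER = rdMolStandardize.TautomerEnumerator()


def _parse(smiles: str) -> Chem.Mol:
    if not smiles:
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def standardize_structure(raw_smiles: str) -> str:
    """Return the standardized canonical SMILES for ``raw_smiles``.

    Largest fragment by heavy-atom count (ties broken by canonical-SMILES
    lexicographic order), charges neutralized, canonical tautomer, all
    stereo annotations removed. Idempotent: the output is a fixed point.
    """
    mol = _parse(raw_smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        # largest fragment wins; lexicographic canonical SMILES breaks ties
        mol = min(frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    mol = _UNCHARGER.uncharge(mol)
    mol = _TAUTOMER.Canonicalize(mol)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def compute_ecfp4(canonical_smiles: str, n_bits: int = N_BITS_DEFAULT) -> np.ndarray:
    """Radius-2 Morgan (ECFP4) fingerprint folded to ``n_bits``, as uint8 0/1."""
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    mol = _parse(canonical_smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


def molecular_weight(canonical_smiles: str) -> float:
    """Average molecular weight in daltons, implicit hydrogens included."""
    return float(Descriptors.MolWt(_parse(canonical_smiles)))


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bit vectors.

    Two all-zero fingerprints are defined maximally dissimilar (0.0): an
    empty fingerprint carries no evidence of similarity.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def bulk_tanimoto(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix between two 0/1 fingerprint matrices.

    Rows of the result index ``fps_a``; all-zero vs all-zero pairs get 0.
    """
    a = np.asarray(fps_a, dtype=np.float32)
    b = np.asarray(fps_b, dtype=np.float32)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def prepare_compounds(
    entries: Iterable[tuple[str, str]], n_bits: int = N_BITS_DEFAULT
) -> list[CompoundRecord]:
    """Standardize and featurize ``(compound_id, raw_smiles)`` pairs.

    Unparseable entries raise; callers that want to skip bad rows should
    filter first.
    """
    records = []
    for compound_id, raw in entries:
        canonical = standardize_structure(raw)
        records.append(
            CompoundRecord(
                compound_id=str(compound_id),
                raw_smiles=raw,
                canonical_smiles=canonical,
                fingerprint=compute_ecfp4(canonical, n_bits),
                mol_weight=molecular_weight(canonical),
            )
        )
    return records


def fingerprint_matrix(records: Sequence[CompoundRecord]) -> np.ndarray:
    """Stack record fingerprints into an (n_compounds, n_bits) uint8 matrix."""
    if not records:
        return np.zeros((0, N_BITS_DEFAULT), dtype=np.uint8)
    return np.stack([r.fingerprint for r in records]).astype(np.uint8)


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a SMILES file: one molecule per line, ``SMILES[<ws>id]``.

    Lines without an id column get a positional id ``C000001``-style.
    """
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"C{i + 1:06d}"
            out.append((cid, smiles))
    return out


def read_sdf(path) -> list[tuple[str, str]]:
    """Read an SDF file into ``(compound_id, smiles)`` pairs."""
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"C{i + 1:06d}"
        out.append((cid, Chem.MolToSmiles(mol)))
    return out


def write_compound_table(records: Sequence[CompoundRecord], path) -> None:
    """Write compound_id, canonical_smiles, mol_weight as CSV."""
    import pandas as pd

    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "canonical_smiles": [r.canonical_smiles for r in records],
            "mol_weight": [r.mol_weight for r in records],
        }
    ).to_csv(path, index=False)


def write_fingerprint_store(records: Sequence[CompoundRecord], prefix) -> None:
    """Write a dense fingerprint matrix (.npy) with a JSON sidecar.

    The sidecar records n_bits and row order so the matrix is
    self-describing when reloaded.
    """
    import json
    from pathlib import Path

    prefix = Path(prefix)
    mat = fingerprint_matrix(records)
    np.save(prefix.with_suffix(".npy"), mat)
    sidecar = {
        "n_bits": int(mat.shape[1]),
        "compound_ids": [r.compound_id for r in records],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_fingerprint_store(prefix) -> tuple[np.ndarray, list[str]]:
    """Read the matrix + sidecar written by :func:`write_fingerprint_store`."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    mat = np.load(prefix.with_suffix(".npy"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    if mat.shape[1] != sidecar["n_bits"]:
        raise ValueError("fingerprint store sidecar disagrees with matrix width")
    return mat, list(sidecar["compound_ids"])
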