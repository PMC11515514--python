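"""Molecular representations: Morgan fingerprints and featurized graphs.

Two representations of a molecule are supported, mirroring the usual
choice in low-data molecular machine learning:

* binary circular (Morgan) fingerprints, default length 1024 and
  radius 3, computed with RDKit;
* heavy-atom molecular graphs with one-hot/real-valued atom and bond
  feature blocks plus a symmetric adjacency matrix, the input to the
  graph attention encoder.

Tanimoto similarity utilities on fingerprints are also provided; the
Tanimoto distance (1 - similarity) to a training set is the
applicability-domain coordinate used by :mod:`molnp.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Fingerprint",
    "MolecularGraph",
    "InvalidSmilesError",
    "smiles_to_fingerprint",
    "smiles_to_graph",
    "tanimoto",
    "max_similarity_to_reference",
    "fingerprint_matrix",
    "read_smiles_file",
    "featurizer_config",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
]


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Fingerprint:
    """Binary circular fingerprint of a molecule."""

    bits: np.ndarray
    n_bits: int
    radius: int

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.shape != (self.n_bits,):
            raise ValueError("bits length must equal n_bits")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    @property
    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class MolecularGraph:
    """Heavy-atom graph with featurized atoms and directed bonds.

    ``bond_features`` maps each directed edge ``(i, j)`` to its feature
    vector; both directions of every bond are present.  Hydrogens are
    implicit: they enter only through the n-H-neighbours atom feature.
    """

    n_atoms: int
    atom_features: np.ndarray          # (n_atoms, d_atom)
    bond_features: dict[tuple[int, int], np.ndarray]
    adjacency: np.ndarray              # (n_atoms, n_atoms), binary symmetric
    source_smiles: str = ""

    def neighbours(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])


# ----------------------------------------------------------- featurization
_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si"]
_HYBRID = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
    Chem.BondStereo.STEREOANY,
]
_MAX_COUNT = 6          # neighbour counts capped with an overflow bin
_CHARGES = [-2, -1, 0, 1, 2]

_PT = Chem.GetPeriodicTable()


def _one_hot(value, choices, with_other: bool = True) -> list[float]:
    vec = [1.0 if value == c else 0.0 for c in choices]
    if with_other:
        vec.append(0.0 if any(vec) else 1.0)
    return vec


def _count_one_hot(n: int) -> list[float]:
    # bins 0..6 plus overflow
    vec = [0.0] * (_MAX_COUNT + 2)
    vec[min(n, _MAX_COUNT + 1)] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    feats = _one_hot(atom.GetSymbol(), _ELEMENTS)
    feats += _count_one_hot(atom.GetTotalNumHs())
    feats += _count_one_hot(atom.GetDegree())
    feats += _one_hot(atom.GetFormalCharge(), _CHARGES)
    feats += _one_hot(atom.GetHybridization(), _HYBRID)
    feats.append(1.0 if atom.IsInRing() else 0.0)
    feats.append(1.0 if atom.GetIsAromatic() else 0.0)
    feats.append(0.0 if atom.GetChiralTag() == Chem.ChiralType.CHI_UNSPECIFIED
                 else 1.0)
    num = atom.GetAtomicNum()
    feats.append(atom.GetMass() / 100.0)
    feats.append(_PT.GetRvdw(num))
    feats.append(_PT.GetRcovalent(num))
    return feats


def _bond_features(bond: Chem.Bond) -> list[float]:
    feats = _one_hot(bond.GetBondType(), _BOND_TYPES, with_other=False)
    feats.append(1.0 if bond.GetIsConjugated() else 0.0)
    feats.append(1.0 if bond.IsInRing() else 0.0)
    feats += _one_hot(bond.GetStereo(), _STEREO, with_other=False)
    return feats


ATOM_FEATURE_DIM = (len(_ELEMENTS) + 1 + 2 * (_MAX_COUNT + 2)
                    + len(_CHARGES) + 1 + len(_HYBRID) + 1 + 3 + 3)
BOND_FEATURE_DIM = len(_BOND_TYPES) + 2 + len(_STEREO)


def featurizer_config() -> dict:
    """Serializable description of the featurizer; stored in checkpoints
    so dimension mismatches between a model and its inputs are detectable."""
    return {
        "elements": _ELEMENTS,
        "max_count": _MAX_COUNT,
        "charges": _CHARGES,
        "d_atom": ATOM_FEATURE_DIM,
        "d_bond": BOND_FEATURE_DIM,
    }


def _parse(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str):
        raise InvalidSmilesError(f"SMILES must be a string, got {type(smiles)}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"could not parse SMILES {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise InvalidSmilesError(f"no heavy atoms in SMILES {smiles!r}")
    return mol


def smiles_to_fingerprint(smiles: str, n_bits: int = 1024,
                          radius: int = 3) -> Fingerprint:
    """Binary Morgan fingerprint of a molecule (default 1024 bits, radius 3)."""
    mol = _parse(smiles)
    bv = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits, n_bits=n_bits, radius=radius)


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Featurized heavy-atom graph of a molecule."""
    mol = _parse(smiles)
    n = mol.GetNumAtoms()
    if n == 0:
        raise InvalidSmilesError(f"no heavy atoms in SMILES {smiles!r}")
    atom_feats = np.array([_atom_features(a) for a in mol.GetAtoms()],
                          dtype=np.float64)
    adjacency = np.zeros((n, n), dtype=np.float64)
    bond_feats: dict[tuple[int, int], np.ndarray] = {}
    for bond in mol.GetBonds():
        i = bond.GetBeginAtomIdx()
        j = bond.GetEndAtomIdx()
        f = np.array(_bond_features(bond), dtype=np.float64)
        adjacency[i, j] = adjacency[j, i] = 1.0
        bond_feats[(i, j)] = f
        bond_feats[(j, i)] = f
    return MolecularGraph(n_atoms=n, atom_features=atom_feats,
                          bond_features=bond_feats, adjacency=adjacency,
                          source_smiles=smiles)


# ------------------------------------------------------------- similarity
def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two fingerprints.

    Two all-zero fingerprints are identical empty sets and score 1.0.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}")
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        return 1.0
    return inter / union


def fingerprint_matrix(fps: list[Fingerprint]) -> np.ndarray:
    """Stack fingerprints into a (n, n_bits) float matrix."""
    if not fps:
        raise ValueError("empty fingerprint list")
    n_bits = fps[0].n_bits
    if any(fp.n_bits != n_bits for fp in fps):
        raise ValueError("fingerprints have inconsistent lengths")
    return np.stack([fp.bits for fp in fps]).astype(np.float64)


def tanimoto_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between rows of two binary matrices."""
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-12), 1.0)
    return sim


def max_similarity_to_reference(queries: list[Fingerprint],
                                reference: list[Fingerprint]) -> np.ndarray:
    """Per query, Tanimoto similarity to its closest reference molecule."""
    if not reference:
        raise ValueError("reference set is empty")
    q = fingerprint_matrix(queries)
    r = fingerprint_matrix(reference)
    if q.shape[1] != r.shape[1]:
        raise ValueError("query/reference fingerprint lengths differ")
    return tanimoto_matrix(q, r).max(axis=1)


# ---------------------------------------------------------------- file IO
def read_smiles_file(path, column: str | None = None) -> list[str]:
    """Read SMILES from plain text (one per line) or a CSV/TSV column."""
    if column is None:
        with open(path) as fh:
            return [line.strip() for line in fh
                    if line.strip() and not line.startswith("#")]
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if column not in df.columns:
        raise ValueError(f"column {column!r} not found in {path}")
    return df[column].astype(str).tolist()
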