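"""Desk-scale synthetic meta-datasets and score-table utilities.

Three kinds of inputs are produced here:

* **Sinusoid families** ``A sin(rho (x - B))`` with task-specific
  amplitude and phase — the classic meta-learning regression benchmark.
  Changing the frequency ``rho`` between meta-training and meta-testing
  creates the divergent-task setting used to study meta-generalization.
* **Synthetic molecular meta-datasets**: tasks are linear functions of
  Morgan fingerprint bits with a tunable shared component.  With shared
  weight fraction ``lambda = 1`` all tasks are perfectly correlated;
  with ``lambda = 0`` they are unrelated.  This emulates a complete
  docking-score matrix (every molecule labelled for every task) at any
  size, with inter-task correlation under experimental control.
* **Score tables** in the DOCKSTRING layout: a TSV with a SMILES
  column, an optional train/test split column, and one numeric column
  per target, complete (no missing entries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .molrep import (InvalidSmilesError, fingerprint_matrix,
                     smiles_to_fingerprint)
from .np_core import TaskObservations

__all__ = [
    "SinusoidFamily", "SyntheticMolTaskSpec", "DockstringMatrix",
    "sample_sinusoid_task", "make_sinusoid_metadataset", "random_smiles",
    "fixture_smiles", "make_molecular_metadataset", "read_dockstring_table",
    "write_dockstring_table", "target_max_correlation", "make_fsl_split",
    "FSLSplit",
]


# ---------------------------------------------------------------- sinusoids
@dataclass
class SinusoidFamily:
    """Task family ``y = A sin(rho (x - B)) + noise``.

    Amplitude and phase are drawn per task; frequency ``rho`` is shared
    by the family (the meta-test shift changes ``rho`` only).
    """

    A_range: tuple[float, float] = (0.1, 5.0)
    B_range: tuple[float, float] = (0.0, float(np.pi))
    rho: float = 1.0
    noise_sd: float = 0.0
    x_range: tuple[float, float] = (-5.0, 5.0)

    def __post_init__(self):
        if self.A_range[0] > self.A_range[1] or self.B_range[0] > self.B_range[1]:
            raise ValueError("parameter ranges must be nonempty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def sample_sinusoid_task(family: SinusoidFamily, n_points: int,
                         rng: np.random.Generator,
                         return_params: bool = False):
    """Draw one sinusoid task observed at ``n_points`` random inputs."""
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    A = rng.uniform(*family.A_range)
    B = rng.uniform(*family.B_range)
    x = rng.uniform(family.x_range[0], family.x_range[1], size=n_points)
    y = A * np.sin(family.rho * (x - B))
    if family.noise_sd > 0:
        y = y + rng.normal(0.0, family.noise_sd, size=n_points)
    task = TaskObservations(x[:, None], y)
    if return_params:
        return task, (A, B)
    return task


def make_sinusoid_metadataset(family: SinusoidFamily, n_tasks: int,
                              n_points: int, rng: np.random.Generator
                              ) -> list[TaskObservations]:
    return [sample_sinusoid_task(family, n_points, rng)
            for _ in range(n_tasks)]


# ------------------------------------------------------------ random SMILES
# Fragments that concatenate into valid SMILES (ring-closure digits are
# reusable once closed, so plain string joins stay parseable).
_FRAGMENTS = [
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1", "c1cnccn1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "C1CCCC1",
    "CC", "CCC", "CC(C)", "CCO", "CCN", "COC", "CNC", "CCS",
    "C(F)(F)F", "C(=O)O", "C(=O)N", "C(=O)C", "S(=O)(=O)C",
    "CCl", "CBr", "CF", "C#N", "C=C", "CO", "CN",
]


def random_smiles(n: int, rng: np.random.Generator,
                  max_fragments: int = 4) -> list[str]:
    """Generate ``n`` unique valid drug-like-ish SMILES strings.

    Molecules are assembled by concatenating random fragments and kept
    only if RDKit parses them; output is canonicalized and de-duplicated,
    so the same rng state always yields the same list.
    """
    from rdkit import Chem

    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("SMILES generation stalled; lower n")
        k = int(rng.integers(1, max_fragments + 1))
        idx = rng.integers(0, len(_FRAGMENTS), size=k)
        smi = "".join(_FRAGMENTS[i] for i in idx)
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() < 3:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    return out


def fixture_smiles() -> list[str]:
    """The bundled list of ~200 valid molecules for offline tests."""
    text = resources.files("molnp").joinpath("data/fixture_smiles.smi").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


# ------------------------------------------------- molecular meta-datasets
@dataclass
class SyntheticMolTaskSpec:
    """Generator settings for a synthetic molecular meta-dataset.

    Task i's labels are a standardized sparse linear function of
    fingerprint bits, ``(lambda w_shared + (1 - lambda) w_i) . fp``,
    plus Gaussian noise: ``shared_weight_fraction`` (lambda) tunes
    inter-task correlation from unrelated (0) to identical (1).
    """

    n_tasks: int = 50
    shared_weight_fraction: float = 0.7
    n_active_bits: int = 32
    noise_sd: float = 0.1
    n_bits: int = 1024
    radius: int = 3

    def __post_init__(self):
        if not (0.0 <= self.shared_weight_fraction <= 1.0):
            raise ValueError("shared_weight_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _sparse_weights(n_bits: int, n_active: int, rng: np.random.Generator
                    ) -> np.ndarray:
    w = np.zeros(n_bits)
    idx = rng.choice(n_bits, size=min(n_active, n_bits), replace=False)
    w[idx] = rng.normal(0.0, 1.0, size=len(idx))
    return w


def make_molecular_metadataset(smiles: list[str], spec: SyntheticMolTaskSpec,
                               rng: np.random.Generator
                               ) -> list[TaskObservations]:
    """One TaskObservations per task, all over the same molecules."""
    if len(smiles) < 2:
        raise ValueError("need at least 2 molecules")
    failures = []
    fps = []
    for smi in smiles:
        try:
            fps.append(smiles_to_fingerprint(smi, spec.n_bits, spec.radius))
        except InvalidSmilesError:
            failures.append(smi)
    if failures:
        raise InvalidSmilesError(
            f"fingerprint computation failed for: {failures}")
    F = fingerprint_matrix(fps)
    lam = spec.shared_weight_fraction
    w_shared = _sparse_weights(spec.n_bits, spec.n_active_bits, rng)
    tasks = []
    for _ in range(spec.n_tasks):
        w_i = _sparse_weights(spec.n_bits, spec.n_active_bits, rng)
        signal = F @ (lam * w_shared + (1.0 - lam) * w_i)
        sd = signal.std()
        if sd > 0:
            signal = (signal - signal.mean()) / sd
        y = signal + rng.normal(0.0, spec.noise_sd, size=len(signal))
        tasks.append(TaskObservations(F.copy(), y))
    return tasks


# ----------------------------------------------------------- score tables
@dataclass
class DockstringMatrix:
    """Complete molecules-by-targets score matrix with optional split."""

    smiles: list[str]
    target_names: list[str]
    scores: np.ndarray                       # (n_molecules, n_targets)
    split: np.ndarray | None = None          # "train"/"test" per molecule

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n, m = len(self.smiles), len(self.target_names)
        if self.scores.shape != (n, m):
            raise ValueError("score matrix shape does not match headers")
        if np.isnan(self.scores).any():
            raise ValueError("score matrix contains missing values")
        if len(set(self.smiles)) != n:
            raise ValueError("duplicate SMILES in matrix")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if len(self.split) != n:
                raise ValueError("split labels do not match molecule count")

    def column(self, name: str) -> np.ndarray:
        return self.scores[:, self.target_names.index(name)]


def read_dockstring_table(path, on_missing: str = "error") -> DockstringMatrix:
    """Read a DOCKSTRING-style TSV (SMILES column, optional ``split``
    column, numeric target columns).

    ``on_missing`` is "error" (default) or "drop" (rows with blank
    scores are removed).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols:
        raise ValueError(f"no 'smiles' column in header of {path}: "
                         f"{list(df.columns)}")
    smiles_col = cols["smiles"]
    split_col = cols.get("split")
    target_cols = [c for c in df.columns if c not in (smiles_col, split_col)]
    if not target_cols:
        raise ValueError(f"no target columns in {path}")
    for c in target_cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0])
            raise ValueError(
                f"non-numeric score in column {c!r}, row {row} of {path}: "
                f"{df[c].iloc[row]!r}")
        df[c] = converted
    missing = df[target_cols].isna().any(axis=1)
    if missing.any():
        if on_missing == "drop":
            df = df[~missing].reset_index(drop=True)
        else:
            row = int(np.flatnonzero(missing.values)[0])
            raise ValueError(f"missing score(s) in row {row} of {path}; "
                             "pass on_missing='drop' to discard such rows")
    smiles = df[smiles_col].astype(str).tolist()
    dupes = df[smiles_col][df[smiles_col].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate SMILES in {path}: {dupes[:5]}")
    split = df[split_col].to_numpy() if split_col else None
    return DockstringMatrix(smiles=smiles, target_names=target_cols,
                            scores=df[target_cols].to_numpy(float),
                            split=split)


def write_dockstring_table(matrix: DockstringMatrix, path) -> None:
    data = {"smiles": matrix.smiles}
    if matrix.split is not None:
        data["split"] = matrix.split
    for j, name in enumerate(matrix.target_names):
        data[name] = matrix.scores[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def target_max_correlation(matrix: DockstringMatrix) -> dict[str, float]:
    """Per target, the highest Pearson correlation to any other target.

    This is the similarity diagnostic used to pick meta-test tasks with
    high/medium/low resemblance to the remaining tasks.  Pairs involving
    a constant column are skipped with a warning.
    """
    m = len(matrix.target_names)
    if m < 2:
        raise ValueError("need at least 2 targets")
    if len(matrix.smiles) < 3:
        raise ValueError("need at least 3 molecules")
    stds = matrix.scores.std(axis=0)
    constant = stds == 0
    if constant.any():
        names = [matrix.target_names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant score column(s) skipped: {names}",
                      stacklevel=2)
    out: dict[str, float] = {}
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(matrix.scores.T)
    for i, name in enumerate(matrix.target_names):
        if constant[i]:
            out[name] = float("nan")
            continue
        others = [corr[i, j] for j in range(m)
                  if j != i and not constant[j]]
        out[name] = float(max(others)) if others else float("nan")
    return out


# ------------------------------------------------------------- FSL splits
@dataclass
class FSLSplit:
    """Few-shot-learning split across tasks and molecules.

    Meta-training uses ``ftrain`` tasks on ``dtrain`` molecules;
    meta-test contexts are drawn from ``ftest`` tasks on ``dtrain``
    molecules and evaluation happens on ``ftest`` tasks on ``dtest``.
    """

    ftrain: list[str]
    ftest: list[str]
    dtrain_idx: np.ndarray
    dtest_idx: np.ndarray


def make_fsl_split(matrix: DockstringMatrix, meta_test_targets: list[str],
                   n_dtrain: int, n_dtest: int, rng: np.random.Generator
                   ) -> FSLSplit:
    """Sample an FSL split, consuming the matrix's train/test labels."""
    if matrix.split is None:
        raise ValueError("matrix has no split labels; a molecule split "
                         "must be provided, not computed here")
    unknown = [t for t in meta_test_targets if t not in matrix.target_names]
    if unknown:
        raise ValueError(f"unknown meta-test targets: {unknown}")
    ftest = list(meta_test_targets)
    ftrain = [t for t in matrix.target_names if t not in ftest]
    if not ftrain:
        raise ValueError("meta-test targets cover every task")
    train_rows = np.flatnonzero(matrix.split == "train")
    test_rows = np.flatnonzero(matrix.split == "test")
    if len(train_rows) < n_dtrain:
        raise ValueError(f"only {len(train_rows)} train-split rows, "
                         f"need {n_dtrain}")
    if len(test_rows) < n_dtest:
        raise ValueError(f"only {len(test_rows)} test-split rows, "
                         f"need {n_dtest}")
    dtrain = rng.choice(train_rows, size=n_dtrain, replace=False)
    dtest = rng.choice(test_rows, size=n_dtest, replace=False)
    return FSLSplit(ftrain=ftrain, ftest=ftest,
                    dtrain_idx=np.sort(dtrain), dtest_idx=np.sort(dtest))
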