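"""Batched Bayesian optimization over a fixed molecular library.

The search loop emulates iterative screening: starting from a random
initial batch, the surrogate model is conditioned on every molecule
evaluated so far (for a neural process, the seen molecules are its
contexts), every unseen candidate is scored, and the best ``batch_size``
candidates are evaluated next, until the evaluation budget is spent.
All objectives are minimized (docking-score convention; negate a
maximization objective at ingestion), so the lower-confidence-bound
acquisition is ``mu - kappa * sigma`` and greedy is ``mu``.

An exact Gaussian-process baseline with a Tanimoto kernel on binary
fingerprints is included, along with the task-augmentation scheme that
manufactures meta-training tasks from a complete score matrix (random
linear/nonlinear transforms of target columns combined with a
drug-likeness score, excluding any targets that enter the objective).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .molrep import Fingerprint, fingerprint_matrix, tanimoto_matrix
from .np_core import ContextSet, NPModel, PredictiveGaussian
from .meta_train import chunked_predict

__all__ = ["CandidateLibrary", "BOConfig", "Trajectory", "AugmentedTask",
           "BOAborted", "lcb", "select_batch", "run_bo", "np_surrogate",
           "perfect_surrogate", "tanimoto_gp_surrogate", "augment_tasks",
           "tanimoto_gp_fit_predict"]


class BOAborted(RuntimeError):
    """Surrogate failure mid-run; carries the partial trajectory."""

    def __init__(self, message: str, trajectory: "Trajectory"):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class CandidateLibrary:
    """Fixed candidate pool with a hidden objective.

    Objective values are only reachable through :meth:`evaluate`, which
    marks molecules as seen — the BO loop never peeks at unseen labels.
    """

    x: object                               # (n, d) array or list of graphs
    objective: np.ndarray                   # hidden values, minimized
    smiles: list[str] | None = None
    seen: np.ndarray = field(init=False)

    def __post_init__(self):
        self.objective = np.asarray(self.objective, float).ravel()
        if len(self.objective) != self.size:
            raise ValueError("objective length must match candidates")
        if self.smiles is not None:
            if len(self.smiles) != self.size:
                raise ValueError("smiles length must match candidates")
            if len(set(self.smiles)) != self.size:
                raise ValueError("library molecules must be unique")
        self.seen = np.zeros(self.size, dtype=bool)

    @property
    def size(self) -> int:
        return len(self.x)

    def evaluate(self, indices) -> np.ndarray:
        indices = np.asarray(indices, int)
        self.seen[indices] = True
        return self.objective[indices]

    def seen_contexts(self) -> ContextSet:
        idx = np.flatnonzero(self.seen)
        if isinstance(self.x, np.ndarray):
            xs = self.x[idx]
        else:
            xs = [self.x[i] for i in idx]
        return ContextSet(xs, self.objective[idx])


@dataclass
class BOConfig:
    batch_size: int = 5
    budget: int = 1000
    acquisition: str = "lcb"                # lcb | greedy | random
    kappa: float = 1.0
    n_init: int = 20

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.budget < self.n_init:
            raise ValueError("budget must cover the initial batch")
        if self.acquisition not in ("lcb", "greedy", "random"):
            raise ValueError("acquisition must be lcb, greedy or random")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass
class Trajectory:
    """Record of one BO run: selections, values, best-so-far curve."""

    selected: list = field(default_factory=list)     # per iteration, indices
    values: list = field(default_factory=list)       # per iteration, values
    best_so_far: list = field(default_factory=list)  # per iteration

    @property
    def n_evaluated(self) -> int:
        return sum(len(s) for s in self.selected)

    @property
    def final_best(self) -> float:
        return self.best_so_far[-1]

    def write_tsv(self, path, smiles: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("iteration\tindex\tsmiles\tobjective\tbest_so_far\n")
            for it, (idx, vals, best) in enumerate(
                    zip(self.selected, self.values, self.best_so_far)):
                for i, v in zip(idx, vals):
                    smi = smiles[i] if smiles else ""
                    fh.write(f"{it}\t{i}\t{smi}\t{v:.6g}\t{best:.6g}\n")


# ------------------------------------------------------------ acquisition
def lcb(pred: PredictiveGaussian, kappa: float) -> np.ndarray:
    """Lower confidence bound ``mu - kappa * sigma`` (lower is better)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return pred.mean - kappa * pred.std


def select_batch(scores: np.ndarray, seen: np.ndarray, batch_size: int
                 ) -> np.ndarray:
    """Indices of the ``batch_size`` best-scoring unseen candidates.

    Ties are broken by lowest index (stable sort).
    """
    scores = np.asarray(scores, float).ravel()
    unseen = np.flatnonzero(~np.asarray(seen, bool))
    if len(unseen) < batch_size:
        raise ValueError(f"only {len(unseen)} unseen candidates, "
                         f"need {batch_size}")
    order = unseen[np.argsort(scores[unseen], kind="stable")]
    return order[:batch_size]


# -------------------------------------------------------------- surrogates
def np_surrogate(model: NPModel, max_chunk: int = 2048,
                 finetune_config=None, rng: np.random.Generator | None = None):
    """Score candidates with a neural process conditioned on seen points.

    With ``finetune_config`` set, the model is first adapted to the seen
    data (when enough contexts have accumulated) before predicting.
    """

    def scorer(contexts: ContextSet, target_x) -> PredictiveGaussian:
        mdl = model
        if finetune_config is not None and contexts.size >= (
                finetune_config.c_new + finetune_config.t_new):
            from .adapt import finetune

            mdl = finetune(model, contexts, finetune_config,
                           rng or np.random.default_rng(0))
        return chunked_predict(mdl, contexts, target_x, max_chunk)

    return scorer


def perfect_surrogate(true_values: np.ndarray):
    """Oracle surrogate predicting the true objective with tiny variance."""
    true_values = np.asarray(true_values, float).ravel()

    def scorer(contexts: ContextSet, target_x) -> PredictiveGaussian:
        return PredictiveGaussian(mean=true_values,
                                  variance=np.full(len(true_values), 1e-12))

    return scorer


def tanimoto_gp_surrogate(noise: float = 0.1):
    """Exact Tanimoto-kernel GP surrogate over binary fingerprint rows."""

    def scorer(contexts: ContextSet, target_x) -> PredictiveGaussian:
        return _gp_fit_predict_matrix(np.asarray(contexts.x, float),
                                      contexts.y,
                                      np.asarray(target_x, float), noise)

    return scorer


# ---------------------------------------------------------------- the loop
def run_bo(surrogate, library: CandidateLibrary, config: BOConfig,
           rng: np.random.Generator) -> Trajectory:
    """Run batched BO; returns the trajectory of selections.

    ``surrogate`` is a callable ``(ContextSet, target_x) ->
    PredictiveGaussian`` over all library candidates (ignored for random
    acquisition).  On surrogate failure, :class:`BOAborted` is raised
    with the partial trajectory attached.
    """
    if library.size <= config.budget:
        raise ValueError("library must be larger than the budget")
    traj = Trajectory()
    init = rng.choice(library.size, size=config.n_init, replace=False)
    vals = library.evaluate(init)
    traj.selected.append(init)
    traj.values.append(vals)
    traj.best_so_far.append(float(vals.min()))
    while traj.n_evaluated + config.batch_size <= config.budget:
        if config.acquisition == "random":
            unseen = np.flatnonzero(~library.seen)
            batch = rng.choice(unseen, size=config.batch_size, replace=False)
        else:
            try:
                pred = surrogate(library.seen_contexts(), library.x)
            except Exception as exc:      # abort but keep what we have
                raise BOAborted(f"surrogate failed after "
                                f"{traj.n_evaluated} evaluations: {exc}",
                                traj) from exc
            scores = (lcb(pred, config.kappa)
                      if config.acquisition == "lcb" else pred.mean)
            batch = select_batch(scores, library.seen, config.batch_size)
        vals = library.evaluate(batch)
        traj.selected.append(batch)
        traj.values.append(vals)
        traj.best_so_far.append(min(traj.best_so_far[-1], float(vals.min())))
    return traj


# --------------------------------------------------------- augmentation
@dataclass
class AugmentedTask:
    """A meta-training task manufactured from a score matrix."""

    description: dict
    labels: np.ndarray
    source_targets: list[str]


def augment_tasks(score_matrix: np.ndarray, target_names: list[str],
                  qed: np.ndarray, n: int, exclude: set[str],
                  rng: np.random.Generator) -> list[AugmentedTask]:
    """Draw ``n`` random transforms of score columns, QED-combined.

    Transforms are uniform over: a scalar multiple of one column; a
    random-weight linear combination of two columns; the elementwise
    minimum or maximum of a column with its median.  Any transform
    touching an excluded target is discarded, so fewer than ``n`` tasks
    may be returned.
    """
    scores = np.asarray(score_matrix, float)
    qed = np.asarray(qed, float).ravel()
    if scores.ndim != 2 or scores.shape[1] != len(target_names):
        raise ValueError("score matrix must be molecules x targets")
    if np.isnan(scores).any():
        raise ValueError("score matrix must be complete")
    if len(qed) != scores.shape[0]:
        raise ValueError("qed must align with molecules")
    if set(target_names) <= set(exclude):
        raise ValueError("exclusion set covers every target")
    medians = np.median(scores, axis=0)
    kinds = ["scalar", "linear2", "min_median", "max_median"]
    out: list[AugmentedTask] = []
    for _ in range(n):
        kind = kinds[rng.integers(0, len(kinds))]
        if kind == "linear2":
            idx = rng.choice(scores.shape[1], size=2, replace=False)
        else:
            idx = np.array([rng.integers(0, scores.shape[1])])
        sources = [target_names[i] for i in idx]
        qed_w = float(rng.uniform(0.5, 2.0))
        weights = rng.uniform(0.1, 1.0, size=len(idx))
        if any(s in exclude for s in sources):
            continue
        if kind == "scalar":
            labels = weights[0] * scores[:, idx[0]]
        elif kind == "linear2":
            labels = scores[:, idx] @ weights
        elif kind == "min_median":
            labels = np.minimum(scores[:, idx[0]], medians[idx[0]])
        else:
            labels = np.maximum(scores[:, idx[0]], medians[idx[0]])
        labels = labels + qed_w * qed
        out.append(AugmentedTask(
            description={"kind": kind, "sources": sources,
                         "weights": weights.tolist(), "qed_weight": qed_w},
            labels=labels, source_targets=sources))
    return out


# ------------------------------------------------------------- Tanimoto GP
def _gp_fit_predict_matrix(train_X: np.ndarray, train_y: np.ndarray,
                           test_X: np.ndarray, noise: float
                           ) -> PredictiveGaussian:
    K = tanimoto_matrix(train_X, train_X)
    Ks = tanimoto_matrix(test_X, train_X)
    y = np.asarray(train_y, float).ravel()
    y_mean = y.mean()
    yc = y - y_mean
    jitter = 0.0
    for _ in range(4):
        try:
            chol = cho_factor(K + (noise + jitter) * np.eye(len(K)),
                              lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = 1e-8 if jitter == 0 else jitter * 100
    else:
        raise np.linalg.LinAlgError("Tanimoto kernel matrix not PSD even "
                                    "with jitter")
    alpha = cho_solve(chol, yc)
    mean = Ks @ alpha + y_mean
    v = cho_solve(chol, Ks.T)
    prior = np.ones(len(test_X))            # Tanimoto self-similarity is 1
    var = prior - np.einsum("ij,ji->i", Ks, v)
    return PredictiveGaussian(mean=mean, variance=np.maximum(var, 1e-12))


def tanimoto_gp_fit_predict(train_fps: list[Fingerprint], train_y,
                            test_fps: list[Fingerprint], noise: float
                            ) -> PredictiveGaussian:
    """Exact GP regression with kernel k(a, b) = Tanimoto(a, b).

    ``noise`` is the observation-noise variance added to the kernel
    diagonal.  The returned variance is the latent posterior variance.
    """
    if noise <= 0:
        raise ValueError("noise must be positive")
    if not train_fps:
        raise ValueError("need at least one training point")
    return _gp_fit_predict_matrix(fingerprint_matrix(train_fps),
                                  train_y, fingerprint_matrix(test_fps),
                                  noise)
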