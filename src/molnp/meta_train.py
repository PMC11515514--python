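"""Randomized context/target sampling and the meta-training loop.

Meta-training visits every task once per epoch.  For each visit the
task's observations are subsampled into a fresh context set and target
set with sizes drawn uniformly from configurable ranges (default
[20, 150)); the predictive log-likelihood of the targets given the
contexts is the per-task objective, averaged over a mini-batch of tasks
for each gradient step.  This randomization of context/target sets is
what protects the models from overfitting: only a fraction of each
task's observations is seen per epoch, keeping the number of *effective
epochs* — the average number of times an individual observation is seen,
``e_e = e * n_bar / O_i`` — low.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Adam
from .np_core import (ContextSet, NPModel, PredictiveGaussian, TargetSet,
                      TaskObservations, batched_cnp_loss_tensor, predict,
                      task_loss_tensor)

__all__ = ["SamplingConfig", "TrainReport", "sample_split",
           "effective_epochs", "meta_train", "chunked_predict",
           "write_train_log"]


@dataclass
class SamplingConfig:
    """How context/target sets are drawn from a task's observations.

    ``fraction`` switches to fraction mode (used by the overfitting
    sweep): both sizes become ``round(fraction * O_i)`` and, with
    ``allow_overlap``, context and target index sets are drawn
    independently so a point may appear in both.
    """

    c_range: tuple[int, int] = (20, 150)
    t_range: tuple[int, int] = (20, 150)
    disjoint: bool = True
    fraction: float | None = None
    allow_overlap: bool = False

    def __post_init__(self):
        for lo, hi in (self.c_range, self.t_range):
            if not (1 <= lo < hi):
                raise ValueError("size ranges must be nonempty with lo >= 1")
        if self.fraction is not None and not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingConfig":
        d = dict(d)
        d["c_range"] = tuple(d["c_range"])
        d["t_range"] = tuple(d["t_range"])
        return cls(**d)


@dataclass
class TrainReport:
    """Per-epoch mean objective plus the configuration that produced it."""

    epoch_objectives: list[float] = field(default_factory=list)
    seed_entropy: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_objectives)


def _draw_sizes(O: int, config: SamplingConfig, rng: np.random.Generator
                ) -> tuple[int, int]:
    c_lo, c_hi = config.c_range
    t_lo, t_hi = config.t_range
    min_sum = c_lo + t_lo
    if config.disjoint and not config.allow_overlap and O < min_sum:
        # small-task rescue: shrink the requested ranges proportionally
        scale = O / min_sum
        c_lo, c_hi = max(1, int(c_lo * scale)), max(2, int(c_hi * scale))
        t_lo, t_hi = max(1, int(t_lo * scale)), max(2, int(t_hi * scale))
    C = int(rng.integers(c_lo, max(c_hi, c_lo + 1)))
    T = int(rng.integers(t_lo, max(t_hi, t_lo + 1)))
    if config.disjoint and not config.allow_overlap and C + T > O:
        factor = O / (C + T)
        C = max(1, int(C * factor))
        T = max(1, int(T * factor))
        while C + T > O:
            if C >= T and C > 1:
                C -= 1
            elif T > 1:
                T -= 1
            else:
                raise ValueError(f"cannot fit a split into {O} observations")
    return C, T


def sample_split(task: TaskObservations, config: SamplingConfig,
                 rng: np.random.Generator) -> tuple[ContextSet, TargetSet]:
    """Draw one context/target split from a task's observations."""
    O = task.n_obs
    if O < 2:
        raise ValueError("need at least 2 observations to split")
    if config.fraction is not None:
        size = max(1, round(config.fraction * O))
        if config.allow_overlap:
            c_idx = rng.permutation(O)[:size]
            t_idx = rng.permutation(O)[:size]
        else:
            if 2 * size > O:
                raise ValueError(
                    f"disjoint fraction splits need 2*{size} <= {O}; "
                    "set allow_overlap=True for fractions above 0.5")
            perm = rng.permutation(O)
            c_idx, t_idx = perm[:size], perm[size: 2 * size]
    else:
        C, T = _draw_sizes(O, config, rng)
        if config.allow_overlap:
            c_idx = rng.permutation(O)[:C]
            t_idx = rng.permutation(O)[:T]
        else:
            perm = rng.permutation(O)
            c_idx, t_idx = perm[:C], perm[C: C + T]
    ctx = task.subset(c_idx)
    tgt = task.subset(t_idx)
    return (ContextSet(ctx.x, ctx.y), TargetSet(tgt.x, tgt.y))


def effective_epochs(e: int, n_bar: float, O_i: int) -> float:
    """Average number of views of an observation: ``e * n_bar / O_i``."""
    if O_i < 1:
        raise ValueError("O_i must be at least 1")
    if e < 0:
        raise ValueError("epoch count must be non-negative")
    return e * n_bar / O_i


def _task_batches(n_tasks: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n_tasks)
    for start in range(0, n_tasks, batch_size):
        yield order[start: start + batch_size]


def meta_train(model: NPModel, tasks: list[TaskObservations],
               config: SamplingConfig, epochs: int,
               rng: np.random.Generator, lr: float = 1e-3,
               batch_size: int = 16, clip_norm: float = 10.0,
               draws: int = 1) -> tuple[NPModel, TrainReport]:
    """Train ``model`` in place on the meta-training tasks.

    Each epoch visits every task once, draws a fresh context/target split
    per task (``draws`` splits if more than one), and takes one Adam step
    per mini-batch of tasks on the mean per-task negative predictive
    log-likelihood.  Raises ``RuntimeError`` if the objective diverges.
    """
    if not tasks:
        raise ValueError("need at least one meta-training task")
    if epochs < 1:
        raise ValueError("epochs must be at least 1")
    opt = Adam(model.parameters(), lr=lr, clip_norm=clip_norm)
    fast = (model.kind == "CNP" and model.graph_encoder is None
            and all(isinstance(t.x, np.ndarray) for t in tasks))
    report = TrainReport(config={"sampling": config.to_dict(),
                                 "lr": lr, "batch_size": batch_size,
                                 "epochs": epochs, "kind": model.kind})
    for _ in range(epochs):
        total, count = 0.0, 0
        for batch_idx in _task_batches(len(tasks), batch_size, rng):
            opt.zero_grad()
            if fast:
                loss = None
                for _d in range(draws):
                    splits = [sample_split(tasks[i], config, rng)
                              for i in batch_idx]
                    term = batched_cnp_loss_tensor(model, splits)
                    loss = term if loss is None else loss + term
                loss = loss * (1.0 / draws)
            else:
                terms = []
                for i in batch_idx:
                    for _d in range(draws):
                        ctx, tgt = sample_split(tasks[i], config, rng)
                        terms.append(task_loss_tensor(model, ctx, tgt, rng))
                loss = terms[0]
                for t in terms[1:]:
                    loss = loss + t
                loss = loss * (1.0 / len(terms))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training objective diverged (loss={float(loss.data)}) "
                    f"after {report.n_epochs} epochs")
            loss.backward()
            opt.step()
            total += float(loss.data) * len(batch_idx)
            count += len(batch_idx)
        report.epoch_objectives.append(total / count)
    return model, report


def chunked_predict(model: NPModel, contexts: ContextSet, target_x,
                    max_chunk: int = 1024) -> PredictiveGaussian:
    """Predict targets in chunks of at most ``max_chunk``.

    Because the decoder acts on each target independently, the result
    matches a single-pass :func:`molnp.np_core.predict` (up to floating
    point) for any chunk size; chunking only bounds peak memory.
    """
    if max_chunk < 1:
        raise ValueError("max_chunk must be at least 1")
    n = len(target_x)
    means, variances = [], []
    for start in range(0, n, max_chunk):
        chunk = (target_x[start: start + max_chunk]
                 if not isinstance(target_x, np.ndarray)
                 else target_x[start: start + max_chunk])
        pred = predict(model, contexts, chunk)
        means.append(pred.mean)
        variances.append(pred.variance)
    return PredictiveGaussian(mean=np.concatenate(means),
                              variance=np.concatenate(variances))


def write_train_log(report: TrainReport, path) -> None:
    """Write the per-epoch objective as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("epoch\tmean_objective\n")
        for i, obj in enumerate(report.epoch_objectives, start=1):
            fh.write(f"{i}\t{obj:.10g}\n")
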