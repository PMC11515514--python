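"""Fine-tuning a neural process on a meta-test task's contexts.

When the meta-test task diverges from the meta-training distribution, an
NP's predictions — including its predictions *on the contexts it was
given* — can be badly off.  Fine-tuning exploits this: the test task's C
labelled contexts are treated as if they were the observations of a
meta-training task, re-split every epoch into fresh disjoint new-context
(C') and new-target (T') sets, and the usual NP objective is
backpropagated.  To limit overfitting only a small parameter subset is
adapted — by default the last two decoder layers (the mean/variance
heads count as the final layer), plus the last two latent-path layers
for an LNP — and everything else stays frozen.

The amount of adaptation is expressed in *effective epochs* (average
views per context point, default 20); the number of actual epochs is
derived from the context size and T'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam
from .np_core import (ContextSet, NPModel, TaskObservations, clone_model,
                      task_loss_tensor)
from .meta_train import SamplingConfig, sample_split

__all__ = ["FineTuneConfig", "epochs_for_effective", "select_adaptable",
           "finetune", "PRESET_20_SHOT"]


@dataclass
class FineTuneConfig:
    """Settings for context-only fine-tuning.

    ``view_count`` chooses the effective-epoch convention: "targets"
    (default) counts only views as a new target, so
    ``e = ceil(e_e * C / T')``; "both" also counts views as a new
    context, ``e = ceil(e_e * C / (C' + T'))``.
    """

    e_e_target: float = 20.0
    c_new: int = 20
    t_new: int = 20
    adaptable: object = "default"     # "default" or list of name prefixes
    lr: float = 1e-4
    view_count: str = "targets"

    def __post_init__(self):
        if self.e_e_target < 0:
            raise ValueError("e_e_target must be non-negative")
        if self.c_new < 1 or self.t_new < 1:
            raise ValueError("c_new and t_new must be at least 1")
        if self.view_count not in ("targets", "both"):
            raise ValueError("view_count must be 'targets' or 'both'")


# preset for the 20-observation few-shot setting
PRESET_20_SHOT = FineTuneConfig(c_new=5, t_new=5)


def epochs_for_effective(e_e: float, C: int, t_new: int) -> int:
    """Actual epochs needed for ``e_e`` effective epochs of adaptation."""
    if C < 1:
        raise ValueError("context size must be at least 1")
    if t_new < 1:
        raise ValueError("t_new must be at least 1")
    if e_e < 0:
        raise ValueError("e_e must be non-negative")
    return int(np.ceil(e_e * C / t_new))


def _default_selection(model: NPModel) -> list:
    layers = model.decoder_layers()[-2:]
    selected = [p for group in layers for p in group]
    if model.kind == "LNP":
        for group in model.latent_layers()[-2:]:
            selected.extend(group)
    return selected


def select_adaptable(model: NPModel, config: FineTuneConfig) -> list:
    """Parameter tensors to adapt; everything else stays frozen."""
    if config.adaptable == "default":
        return _default_selection(model)
    named = model.named_parameters()
    selected = []
    for prefix in config.adaptable:
        matches = [p for name, p in named if name.startswith(prefix)]
        if not matches:
            known = sorted({name.rsplit(".", 1)[0] for name, _ in named})
            raise ValueError(
                f"selector {prefix!r} matches no parameters; known layers: "
                f"{known}")
        selected.extend(m for m in matches if not any(m is s for s in selected))
    return selected


def finetune(model: NPModel, contexts: ContextSet, config: FineTuneConfig,
             rng: np.random.Generator) -> NPModel:
    """Adapt a copy of ``model`` to one test task; the input is untouched.

    Every epoch the C contexts are re-split into disjoint fresh contexts
    (C') and targets (T'), and one Adam step is taken on the NP objective
    using only the adaptable parameter subset.
    """
    C = contexts.size
    if C < config.c_new + config.t_new:
        raise ValueError(
            f"need at least c_new + t_new = {config.c_new + config.t_new} "
            f"contexts, got {C}; lower c_new/t_new (e.g. the 20-shot preset "
            "uses 5/5)")
    adapted = clone_model(model)
    denom = (config.t_new if config.view_count == "targets"
             else config.c_new + config.t_new)
    n_epochs = epochs_for_effective(config.e_e_target, C, denom)
    if n_epochs == 0:
        return adapted
    params = select_adaptable(adapted, config)
    opt = Adam(params, lr=config.lr)
    task = TaskObservations(contexts.x, contexts.y)
    split_cfg = SamplingConfig(c_range=(config.c_new, config.c_new + 1),
                               t_range=(config.t_new, config.t_new + 1))
    for _ in range(n_epochs):
        ctx, tgt = sample_split(task, split_cfg, rng)
        opt.zero_grad()
        loss = task_loss_tensor(adapted, ctx, tgt, rng)
        if not np.isfinite(loss.data):
            raise RuntimeError("fine-tuning objective diverged")
        loss.backward()
        opt.step()
    return adapted
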