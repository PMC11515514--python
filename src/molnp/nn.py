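"""Dense layers, multilayer perceptrons and the Adam optimizer.

Built directly on :mod:`molnp.autodiff`.  Parameters are named so that
subsets can be selected for freezing during fine-tuning and so that
checkpoints round-trip bit-exactly.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Dense", "MLP", "Adam", "named_parameters"]

_ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "leaky_relu": lambda t: t.leaky_relu(),
    "tanh": lambda t: t.tanh(),
}


class Dense:
    """Affine layer ``x @ W + b`` with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense"):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        flat = x.ndim > 2
        if flat:
            lead = x.shape[:-1]
            x = x.reshape(-1, x.shape[-1])
        out = x @ self.W + self.b
        if flat:
            out = out.reshape(*lead, out.shape[-1])
        return out

    def parameters(self):
        return [(f"{self.name}.W", self.W), (f"{self.name}.b", self.b)]


class MLP:
    """Fully connected network; ``sizes`` includes input and output widths.

    The final layer is linear; all hidden layers use ``activation``.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 activation: str = "relu", name: str = "mlp"):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.activation = activation
        self.layers = [Dense(sizes[i], sizes[i + 1], rng, f"{name}.{i}")
                       for i in range(len(sizes) - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        act = _ACTIVATIONS[self.activation]
        for layer in self.layers[:-1]:
            x = act(layer(x))
        return self.layers[-1](x)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out


def named_parameters(*modules) -> list[tuple[str, Tensor]]:
    out = []
    for m in modules:
        out.extend(m.parameters())
    names = [n for n, _ in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate parameter names")
    return out


class Adam:
    """Adam with global gradient-norm clipping.

    Only tensors in ``params`` are updated; anything else on the tape is
    effectively frozen, which is how layer freezing is implemented.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float = 10.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
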