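"""Conditional and latent neural processes.

A neural process (NP) is a meta-learning model that maps a *context set*
of labelled points ``(x_c, y_c)`` to a Gaussian predictive distribution
over the labels of *target* inputs ``x_t``, assuming conditional
independence between targets:

    q(y_t | x_c, y_c; x_t) = prod_j N(y_tj; mu(x_tj, x_c, y_c),
                                       sigma^2(x_tj, x_c, y_c))

Each context point is mapped by an encoder ``h`` to a local encoding
``r_j``; the encodings are averaged into a permutation-invariant global
function encoding ``r``; a decoder ``g`` maps ``(r, x)`` to the predictive
mean and variance.  The conditional NP (CNP) decodes ``r`` directly.  The
latent NP (LNP) instead passes ``r`` through a latent path producing a
diagonal Gaussian over a latent variable ``z``, decodes a sample of ``z``,
and is trained with a variational objective whose KL term regularizes the
posterior given contexts-and-targets toward the one given contexts only.

Inputs ``x`` may be plain real vectors (e.g. fingerprints, 1-D sinusoid
abscissas) or molecular graphs; in the latter case a trainable graph
attention encoder (:mod:`molnp.graph_encoder`) produces a fixed-length
molecular representation that takes the place of ``x``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, stack
from .nn import MLP, Dense, named_parameters

__all__ = [
    "TaskObservations",
    "ContextSet",
    "TargetSet",
    "FunctionEncoding",
    "PredictiveGaussian",
    "LatentDistribution",
    "NPModel",
    "make_cnp",
    "make_lnp",
    "encode_contexts",
    "predict",
    "log_predictive_density",
    "cnp_loss",
    "lnp_posterior",
    "lnp_loss",
    "gaussian_kl",
    "save_model",
    "load_model",
    "VAR_FLOOR",
]

VAR_FLOOR = 1e-4


# ------------------------------------------------------------------- types
@dataclass
class TaskObservations:
    """All labelled observations of one function/task."""

    x: object                    # (O, d) array, or list of graphs/SMILES
    y: np.ndarray                # (O,)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        if len(self.y) != self.n_obs or self.n_obs < 1:
            raise ValueError("x and y must be nonempty and the same length")
        if not np.isfinite(self.y).all():
            raise ValueError("labels must be finite")

    @property
    def n_obs(self) -> int:
        return len(self.x)

    def subset(self, idx) -> "TaskObservations":
        idx = np.asarray(idx)
        if isinstance(self.x, np.ndarray):
            return TaskObservations(self.x[idx], self.y[idx])
        return TaskObservations([self.x[i] for i in idx], self.y[idx])


@dataclass
class ContextSet:
    x: object
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        if len(self.y) != self.size:
            raise ValueError("context x and y lengths differ")

    @property
    def size(self) -> int:
        return len(self.x)


@dataclass
class TargetSet:
    x: object
    y: np.ndarray | None = None

    def __post_init__(self):
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.float64).ravel()
            if len(self.y) != self.size:
                raise ValueError("target x and y lengths differ")

    @property
    def size(self) -> int:
        return len(self.x)


@dataclass
class FunctionEncoding:
    r: np.ndarray
    r_j: np.ndarray | None = None


@dataclass
class PredictiveGaussian:
    """Independent per-target Gaussian predictions."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.variance = np.asarray(self.variance, dtype=np.float64).ravel()
        if self.mean.shape != self.variance.shape:
            raise ValueError("mean and variance shapes differ")
        if not (np.isfinite(self.mean).all() and np.isfinite(self.variance).all()):
            raise FloatingPointError("non-finite prediction")
        if (self.variance <= 0).any():
            raise ValueError("predictive variance must be strictly positive")

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(self.variance)


@dataclass
class LatentDistribution:
    mean: np.ndarray
    variance: np.ndarray


# ------------------------------------------------------------------- model
class NPModel:
    """Weights and configuration of a conditional or latent NP.

    ``kind`` is "CNP" or "LNP".  The decoder is a 3-layer network: two
    hidden dense layers followed by separate mean and raw-variance heads
    (the heads together count as the final decoder layer for the purpose
    of layer selection during fine-tuning).
    """

    def __init__(self, kind: str, x_dim: int, rng: np.random.Generator,
                 r_dim: int = 128, z_dim: int = 64, width: int = 128,
                 var_floor: float = VAR_FLOOR, graph_encoder=None):
        if kind not in ("CNP", "LNP"):
            raise ValueError("kind must be 'CNP' or 'LNP'")
        self.kind = kind
        self.x_dim = int(x_dim)
        self.r_dim = int(r_dim)
        self.z_dim = int(z_dim)
        self.width = int(width)
        self.var_floor = float(var_floor)
        self.graph_encoder = graph_encoder

        self.encoder = MLP([self.x_dim + 1, width, width, r_dim], rng,
                           name="encoder")
        cond_dim = z_dim if kind == "LNP" else r_dim
        self.dec_body = MLP([cond_dim + self.x_dim, width, width], rng,
                            name="decoder.body")
        self.head_mu = Dense(width, 1, rng, name="decoder.head_mu")
        self.head_sigma = Dense(width, 1, rng, name="decoder.head_sigma")
        self.latent = (MLP([r_dim, width, 2 * z_dim], rng, name="latent")
                       if kind == "LNP" else None)

    # -- parameter bookkeeping -------------------------------------------
    def modules(self):
        mods = [self.encoder, self.dec_body, self.head_mu, self.head_sigma]
        if self.latent is not None:
            mods.append(self.latent)
        if self.graph_encoder is not None:
            mods.append(self.graph_encoder)
        return mods

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        return named_parameters(*self.modules())

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def decoder_layers(self) -> list[list[Tensor]]:
        """Decoder parameters grouped by layer, input side first; the
        mean/variance heads form the final layer."""
        groups = [[ly.W, ly.b] for ly in self.dec_body.layers]
        groups.append([self.head_mu.W, self.head_mu.b,
                       self.head_sigma.W, self.head_sigma.b])
        return groups

    def latent_layers(self) -> list[list[Tensor]]:
        if self.latent is None:
            return []
        return [[ly.W, ly.b] for ly in self.latent.layers]

    # -- featurization ---------------------------------------------------
    def featurize(self, x) -> Tensor:
        """Map raw inputs to a (n, x_dim) tensor."""
        if self.graph_encoder is not None:
            from .molrep import MolecularGraph, smiles_to_graph

            graphs = [g if isinstance(g, MolecularGraph) else smiles_to_graph(g)
                      for g in x]
            return stack([self.graph_encoder.encode(g) for g in graphs])
        arr = np.asarray(x, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[1] != self.x_dim:
            raise ValueError(
                f"input dimension {arr.shape} incompatible with model "
                f"x_dim={self.x_dim}")
        return Tensor(arr)

    # -- forward pieces --------------------------------------------------
    def _encode_tensor(self, x, y: np.ndarray) -> tuple[Tensor, Tensor]:
        """Per-context encodings (C, r_dim) and their mean (1, r_dim)."""
        feats = self.featurize(x)
        inp = concatenate([feats, Tensor(np.asarray(y, float)[:, None])], axis=1)
        r_j = self.encoder(inp)
        r = r_j.sum(axis=0, keepdims=True) * (1.0 / max(len(y), 1))
        return r_j, r

    def _decode(self, cond: Tensor, target_feats: Tensor) -> tuple[Tensor, Tensor]:
        """Decode a (1, cond_dim) conditioning vector at target features."""
        t = target_feats.shape[0]
        tiled = cond + Tensor(np.zeros((t, cond.shape[1])))
        h = self.dec_body(concatenate([tiled, target_feats], axis=1))
        mu = self.head_mu(h)
        var = self.head_sigma(h).softplus() + self.var_floor
        return mu.reshape(-1), var.reshape(-1)

    def _latent_params(self, r: Tensor) -> tuple[Tensor, Tensor]:
        out = self.latent(r)
        mu = out[:, : self.z_dim]
        var = out[:, self.z_dim:].softplus() + self.var_floor
        return mu, var


def make_cnp(x_dim: int, rng: np.random.Generator, **kw) -> NPModel:
    return NPModel("CNP", x_dim, rng, **kw)


def make_lnp(x_dim: int, rng: np.random.Generator, **kw) -> NPModel:
    return NPModel("LNP", x_dim, rng, **kw)


# -------------------------------------------------------------- operations
def encode_contexts(model: NPModel, contexts: ContextSet,
                    keep_local: bool = False) -> FunctionEncoding:
    """Permutation-invariant mean aggregation of per-context encodings.

    An empty context set encodes to the zero vector.
    """
    if contexts.size == 0:
        r = np.zeros(model.r_dim)
        return FunctionEncoding(r=r, r_j=np.zeros((0, model.r_dim))
                                if keep_local else None)
    r_j, r = model._encode_tensor(contexts.x, contexts.y)
    return FunctionEncoding(r=r.data.ravel().copy(),
                            r_j=r_j.data.copy() if keep_local else None)


def predict(model: NPModel, contexts: ContextSet, target_x,
            n_samples: int = 1, rng: np.random.Generator | None = None
            ) -> PredictiveGaussian:
    """Gaussian predictive distribution at ``target_x`` given contexts.

    For an LNP the latent variable is decoded at its posterior mean by
    default (deterministic); with ``n_samples > 1`` a Gaussian-mixture
    moment match over posterior samples is returned instead.
    """
    if len(target_x) == 0:
        raise ValueError("target_x must be nonempty")
    target_feats = model.featurize(target_x)
    if contexts.size > 0:
        _, r = model._encode_tensor(contexts.x, contexts.y)
    else:
        r = Tensor(np.zeros((1, model.r_dim)))
    if model.kind == "CNP":
        mu, var = model._decode(r, target_feats)
    else:
        z_mu, z_var = model._latent_params(r)
        if n_samples <= 1:
            mu, var = model._decode(z_mu, target_feats)
        else:
            if rng is None:
                raise ValueError("n_samples > 1 requires an rng")
            mus, vars_ = [], []
            for _ in range(n_samples):
                eps = rng.standard_normal(z_mu.shape)
                z = Tensor(z_mu.data + np.sqrt(z_var.data) * eps)
                m, v = model._decode(z, target_feats)
                mus.append(m.data)
                vars_.append(v.data)
            m = np.mean(mus, axis=0)
            v = np.mean([vv + mm ** 2 for mm, vv in zip(mus, vars_)],
                        axis=0) - m ** 2
            return PredictiveGaussian(mean=m, variance=np.maximum(v, VAR_FLOOR))
    if not (np.isfinite(mu.data).all() and np.isfinite(var.data).all()):
        raise FloatingPointError(
            "non-finite activations in decoder; check input scaling "
            f"(mu range {np.nanmin(mu.data)}..{np.nanmax(mu.data)})")
    return PredictiveGaussian(mean=mu.data.copy(), variance=var.data.copy())


def log_predictive_density(pred: PredictiveGaussian, y) -> float:
    """Sum over points of log N(y_j; mu_j, sigma^2_j)."""
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.shape != pred.mean.shape:
        raise ValueError("label length does not match prediction length")
    var = pred.variance
    ll = -0.5 * (np.log(2 * np.pi * var) + (y - pred.mean) ** 2 / var)
    return float(ll.sum())


def gaussian_kl(mu_q, var_q, mu_p, var_p) -> float:
    """KL( N(mu_q, var_q) || N(mu_p, var_p) ), diagonal, summed."""
    mu_q, var_q = np.asarray(mu_q, float), np.asarray(var_q, float)
    mu_p, var_p = np.asarray(mu_p, float), np.asarray(var_p, float)
    kl = 0.5 * (np.log(var_p / var_q) + (var_q + (mu_q - mu_p) ** 2) / var_p
                - 1.0)
    return float(kl.sum())


# ----------------------------------------------------------- loss tensors
def _nll_tensor(mu: Tensor, var: Tensor, y: np.ndarray) -> Tensor:
    """Summed Gaussian negative log-likelihood as a differentiable scalar."""
    yt = Tensor(np.asarray(y, float).ravel())
    resid = yt - mu
    return (0.5 * (var * (2 * np.pi)).log()
            + 0.5 * resid * resid / var).sum()


def cnp_loss_tensor(model: NPModel, contexts: ContextSet,
                    targets: TargetSet) -> Tensor:
    if targets.y is None:
        raise ValueError("targets must carry labels for the loss")
    target_feats = model.featurize(targets.x)
    if contexts.size > 0:
        _, r = model._encode_tensor(contexts.x, contexts.y)
    else:
        r = Tensor(np.zeros((1, model.r_dim)))
    mu, var = model._decode(r, target_feats)
    return _nll_tensor(mu, var, targets.y)


def cnp_loss(model: NPModel, contexts: ContextSet, targets: TargetSet) -> float:
    """Negative predictive log-likelihood of the targets given the contexts."""
    return float(cnp_loss_tensor(model, contexts, targets).data)


def lnp_posterior(model: NPModel, data: ContextSet) -> LatentDistribution:
    """Diagonal Gaussian over the latent z given labelled data."""
    if model.kind != "LNP":
        raise ValueError("lnp_posterior requires an LNP model")
    if data.size == 0:
        raise ValueError("lnp_posterior requires nonempty data")
    _, r = model._encode_tensor(data.x, data.y)
    z_mu, z_var = model._latent_params(r)
    return LatentDistribution(mean=z_mu.data.ravel().copy(),
                              variance=z_var.data.ravel().copy())


def _kl_tensor(mu_q: Tensor, var_q: Tensor, mu_p: Tensor, var_p: Tensor
               ) -> Tensor:
    d = mu_q - mu_p
    return (0.5 * ((var_p / var_q).log() + (var_q + d * d) / var_p - 1.0)).sum()


def lnp_loss_tensor(model: NPModel, contexts: ContextSet, targets: TargetSet,
                    rng: np.random.Generator) -> Tensor:
    if targets.y is None:
        raise ValueError("targets must carry labels for the loss")
    if model.kind != "LNP":
        raise ValueError("lnp_loss requires an LNP model")
    # posterior given contexts ∪ targets (the variational distribution)
    if isinstance(contexts.x, np.ndarray):
        a = np.asarray(contexts.x, float).reshape(contexts.size, -1)
        b = np.asarray(targets.x, float).reshape(targets.size, -1)
        x_all = np.concatenate([a, b])
        if x_all.shape[1] == 1 and np.asarray(contexts.x).ndim == 1:
            x_all = x_all.ravel()
    else:
        x_all = list(contexts.x) + list(targets.x)
    y_all = np.concatenate([contexts.y, targets.y])
    _, r_all = model._encode_tensor(x_all, y_all)
    q_mu, q_var = model._latent_params(r_all)
    # prior: posterior given contexts only
    if contexts.size > 0:
        _, r_c = model._encode_tensor(contexts.x, contexts.y)
    else:
        r_c = Tensor(np.zeros((1, model.r_dim)))
    p_mu, p_var = model._latent_params(r_c)
    # single reparameterized sample
    eps = rng.standard_normal(q_mu.shape)
    z = q_mu + (q_var ** 0.5) * Tensor(eps)
    target_feats = model.featurize(targets.x)
    mu, var = model._decode(z, target_feats)
    return _nll_tensor(mu, var, targets.y) + _kl_tensor(q_mu, q_var, p_mu, p_var)


def lnp_loss(model: NPModel, contexts: ContextSet, targets: TargetSet,
             rng: np.random.Generator) -> float:
    """Single-sample variational objective: reconstruction NLL + KL."""
    return float(lnp_loss_tensor(model, contexts, targets, rng).data)


def task_loss_tensor(model: NPModel, contexts: ContextSet, targets: TargetSet,
                     rng: np.random.Generator) -> Tensor:
    """The per-task training loss appropriate for the model kind."""
    if model.kind == "CNP":
        return cnp_loss_tensor(model, contexts, targets)
    return lnp_loss_tensor(model, contexts, targets, rng)


# ------------------------------------------------------- batched fast path
def batched_cnp_loss_tensor(model: NPModel, splits) -> Tensor:
    """Mean over tasks of the CNP loss, on padded 3-D batches.

    ``splits`` is a list of ``(ContextSet, TargetSet)`` with plain-vector
    inputs.  Tasks are padded to the largest context/target size in the
    batch and masked, so one tape evaluates the whole batch.
    """
    B = len(splits)
    xd = model.x_dim
    maxc = max(max(c.size for c, _ in splits), 1)
    maxt = max(t.size for _, t in splits)
    Xc = np.zeros((B, maxc, xd))
    Yc = np.zeros((B, maxc))
    Mc = np.zeros((B, maxc))
    Xt = np.zeros((B, maxt, xd))
    Yt = np.zeros((B, maxt))
    Mt = np.zeros((B, maxt))
    for b, (c, t) in enumerate(splits):
        if c.size:
            Xc[b, : c.size] = np.asarray(c.x, float).reshape(c.size, xd)
            Yc[b, : c.size] = c.y
            Mc[b, : c.size] = 1.0
        Xt[b, : t.size] = np.asarray(t.x, float).reshape(t.size, xd)
        Yt[b, : t.size] = t.y
        Mt[b, : t.size] = 1.0
    enc_in = Tensor(np.concatenate([Xc, Yc[..., None]], axis=2))
    r_j = model.encoder(enc_in)                       # (B, maxc, r)
    mask_c = Tensor(Mc[..., None])
    denom = np.maximum(Mc.sum(axis=1), 1.0)[:, None, None]
    r = (r_j * mask_c).sum(axis=1, keepdims=True) * Tensor(1.0 / denom)
    if model.kind == "LNP":
        raise NotImplementedError("batched path is CNP-only")
    cond = r + Tensor(np.zeros((B, maxt, model.r_dim)))
    h = model.dec_body(concatenate([cond, Tensor(Xt)], axis=2))
    mu = model.head_mu(h).reshape(B, maxt)
    var = model.head_sigma(h).reshape(B, maxt).softplus() + model.var_floor
    yt = Tensor(Yt)
    mt = Tensor(Mt)
    nll = (0.5 * (var * (2 * np.pi)).log()
           + 0.5 * (yt - mu) * (yt - mu) / var) * mt
    return nll.sum() * (1.0 / B)


# ---------------------------------------------------------------- storage
def model_config(model: NPModel) -> dict:
    cfg = {
        "kind": model.kind,
        "x_dim": model.x_dim,
        "r_dim": model.r_dim,
        "z_dim": model.z_dim,
        "width": model.width,
        "var_floor": model.var_floor,
        "graph": model.graph_encoder is not None,
    }
    if model.graph_encoder is not None:
        cfg["graph_config"] = model.graph_encoder.config()
    return cfg


def clone_model(model: NPModel) -> NPModel:
    """Independent copy of a model (weights copied, not shared)."""
    cfg = model_config(model)
    rng = np.random.default_rng(0)
    graph_encoder = None
    if cfg["graph"]:
        from .graph_encoder import GraphEncoder

        graph_encoder = GraphEncoder.from_config(cfg["graph_config"], rng)
    twin = NPModel(cfg["kind"], cfg["x_dim"], rng, r_dim=cfg["r_dim"],
                   z_dim=cfg["z_dim"], width=cfg["width"],
                   var_floor=cfg["var_floor"], graph_encoder=graph_encoder)
    src = dict(model.named_parameters())
    for name, p in twin.named_parameters():
        p.data = src[name].data.copy()
    return twin


def save_model(model: NPModel, path) -> None:
    """Write weights + configuration to a single ``.npz`` archive.

    Weights are stored as float64 and round-trip bit-exactly.
    """
    arrays = {name: p.data for name, p in model.named_parameters()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model_config(model)).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> NPModel:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        rng = np.random.default_rng(0)
        graph_encoder = None
        if cfg["graph"]:
            from .graph_encoder import GraphEncoder

            graph_encoder = GraphEncoder.from_config(cfg["graph_config"], rng)
        model = NPModel(cfg["kind"], cfg["x_dim"], rng, r_dim=cfg["r_dim"],
                        z_dim=cfg["z_dim"], width=cfg["width"],
                        var_floor=cfg["var_floor"], graph_encoder=graph_encoder)
        for name, p in model.named_parameters():
            p.data = data[name].copy()
    return model
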