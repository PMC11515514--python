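"""Graph attention encoder producing fixed-length molecular representations.

The encoder turns a featurized heavy-atom graph into a single vector of
length 50 in three stages:

1. **Pre-embedding** — a 2-layer network (50 hidden units) maps each
   atom's features to a length-25 vector; another maps each incident
   bond's features to length 25, and the bond outputs are summed over
   the neighbour set.  Concatenation gives a length-50 atom state.
2. **Neighbour message passing** — 3 rounds of attention over direct
   neighbours.  Queries and keys come from a single-layer network,
   values from a linear map (scaled dot-product, one head); each atom's
   state receives a residual update from its attended message.  Atoms
   with no neighbours pass through unchanged.
3. **Superatom readout** — an auxiliary node connected to every atom is
   added (initialized to the mean atom state) and 3 further attention
   rounds run on the augmented graph; the superatom's final state is
   passed through a small output network to give the length-50
   molecular representation.

There are no gated recurrent units anywhere; updates are residual.  The
whole map is invariant to relabelling of the atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate
from .nn import MLP, Dense
from .molrep import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph

__all__ = ["AtomStates", "AttentionBlock", "GraphEncoder",
           "embed_atoms_and_bonds", "neighbour_message_rounds",
           "superatom_readout"]


@dataclass
class AtomStates:
    """Per-atom encodings at a given stage of the encoder."""

    states: Tensor               # (n_atoms, state_dim)
    stage: str                   # pre | post-neighbour | post-superatom


class AttentionBlock:
    """One round of single-head QKV attention over a neighbour mask."""

    def __init__(self, dim: int, rng: np.random.Generator, name: str):
        self.query = Dense(dim, dim, rng, f"{name}.query")
        self.key = Dense(dim, dim, rng, f"{name}.key")
        self.value = Dense(dim, dim, rng, f"{name}.value")
        self.update = Dense(dim, dim, rng, f"{name}.update")
        self.dim = dim

    def parameters(self):
        out = []
        for mod in (self.query, self.key, self.value, self.update):
            out.extend(mod.parameters())
        return out

    def attention(self, states: Tensor, mask: np.ndarray
                  ) -> tuple[Tensor, np.ndarray]:
        """Attended messages and the attention weights over ``mask``."""
        q = self.query(states).leaky_relu()        # single-layer FNN
        k = self.key(states).leaky_relu()
        v = self.value(states)                     # linear values
        scores = (q @ k.T) * (1.0 / np.sqrt(self.dim))
        # stable masked softmax; rows without neighbours get zero weights
        row_max = np.where(mask.any(axis=1, keepdims=True),
                           np.max(np.where(mask > 0, scores.data, -np.inf),
                                  axis=1, keepdims=True), 0.0)
        e = (scores - Tensor(row_max)).exp() * Tensor(mask)
        denom = e.sum(axis=1, keepdims=True) + 1e-30
        attn = e / denom
        return attn @ v, attn.data.copy()

    def __call__(self, states: Tensor, mask: np.ndarray) -> Tensor:
        msg, _ = self.attention(states, mask)
        has_nb = (mask.sum(axis=1) > 0).astype(float)[:, None]
        return states + Tensor(has_nb) * self.update(msg).leaky_relu()


class GraphEncoder:
    """Trainable molecule-to-vector encoder (default output length 50)."""

    def __init__(self, rng: np.random.Generator, state_dim: int = 50,
                 pre_hidden: int = 50, n_neighbour_rounds: int = 3,
                 n_super_rounds: int = 3,
                 d_atom: int = ATOM_FEATURE_DIM, d_bond: int = BOND_FEATURE_DIM):
        if state_dim % 2 != 0:
            raise ValueError("state_dim must be even (atom/bond halves)")
        half = state_dim // 2
        self.state_dim = state_dim
        self.d_atom = d_atom
        self.d_bond = d_bond
        self.pre_hidden = pre_hidden
        self.n_neighbour_rounds = n_neighbour_rounds
        self.n_super_rounds = n_super_rounds
        self.pre_atom = MLP([d_atom, pre_hidden, half], rng,
                            activation="leaky_relu", name="graph.pre_atom")
        self.pre_bond = MLP([d_bond, pre_hidden, half], rng,
                            activation="leaky_relu", name="graph.pre_bond")
        self.neighbour_blocks = [
            AttentionBlock(state_dim, rng, f"graph.nb{i}")
            for i in range(n_neighbour_rounds)]
        self.super_blocks = [
            AttentionBlock(state_dim, rng, f"graph.super{i}")
            for i in range(n_super_rounds)]
        self.final = MLP([state_dim, pre_hidden, state_dim], rng,
                         activation="leaky_relu", name="graph.final")

    # -- bookkeeping -----------------------------------------------------
    def parameters(self):
        out = self.pre_atom.parameters() + self.pre_bond.parameters()
        for blk in self.neighbour_blocks + self.super_blocks:
            out.extend(blk.parameters())
        out.extend(self.final.parameters())
        return out

    def config(self) -> dict:
        return {"state_dim": self.state_dim, "pre_hidden": self.pre_hidden,
                "n_neighbour_rounds": self.n_neighbour_rounds,
                "n_super_rounds": self.n_super_rounds,
                "d_atom": self.d_atom, "d_bond": self.d_bond}

    @classmethod
    def from_config(cls, cfg: dict, rng: np.random.Generator) -> "GraphEncoder":
        return cls(rng, **cfg)

    # -- stages ----------------------------------------------------------
    def embed(self, graph: MolecularGraph) -> AtomStates:
        if graph.atom_features.shape[1] != self.d_atom:
            raise ValueError(
                f"atom feature dim {graph.atom_features.shape[1]} does not "
                f"match encoder d_atom={self.d_atom}")
        atom_half = self.pre_atom(Tensor(graph.atom_features))
        n = graph.n_atoms
        edges = sorted(graph.bond_features)
        if edges:
            feats = np.stack([graph.bond_features[e] for e in edges])
            if feats.shape[1] != self.d_bond:
                raise ValueError(
                    f"bond feature dim {feats.shape[1]} does not match "
                    f"encoder d_bond={self.d_bond}")
            per_edge = self.pre_bond(Tensor(feats))      # (E, half)
            scatter = np.zeros((n, len(edges)))
            for col, (i, _j) in enumerate(edges):
                scatter[i, col] = 1.0                    # sum at the receiver
            bond_half = Tensor(scatter) @ per_edge
        else:
            bond_half = Tensor(np.zeros((n, self.state_dim // 2)))
        return AtomStates(concatenate([atom_half, bond_half], axis=1), "pre")

    def neighbour_rounds(self, states: AtomStates, graph: MolecularGraph,
                         rounds: int | None = None) -> AtomStates:
        rounds = self.n_neighbour_rounds if rounds is None else rounds
        if rounds < 0:
            raise ValueError("rounds must be non-negative")
        if rounds > len(self.neighbour_blocks):
            raise ValueError("more rounds requested than configured blocks")
        s = states.states
        for i in range(rounds):
            s = self.neighbour_blocks[i](s, graph.adjacency)
        return AtomStates(s, "post-neighbour")

    def superatom(self, states: AtomStates, graph: MolecularGraph,
                  rounds: int | None = None) -> Tensor:
        rounds = self.n_super_rounds if rounds is None else rounds
        if rounds < 0:
            raise ValueError("rounds must be non-negative")
        if rounds > len(self.super_blocks):
            raise ValueError("more rounds requested than configured blocks")
        n = graph.n_atoms
        if n == 0:
            raise ValueError("cannot read out an empty molecule")
        super_init = states.states.mean(axis=0, keepdims=True)
        s = concatenate([states.states, super_init], axis=0)
        adj = np.zeros((n + 1, n + 1))
        adj[:n, :n] = graph.adjacency
        adj[n, :n] = 1.0
        adj[:n, n] = 1.0
        for i in range(rounds):
            s = self.super_blocks[i](s, adj)
        return self.final(s[n:n + 1, :]).reshape(-1)

    def encode(self, graph: MolecularGraph) -> Tensor:
        """Full pipeline: embed, neighbour rounds, superatom readout."""
        return self.superatom(self.neighbour_rounds(self.embed(graph), graph),
                              graph)

    def attention_maps(self, graph: MolecularGraph) -> list[np.ndarray]:
        """Neighbour-round attention matrices (diagnostic, no gradients)."""
        s = self.embed(graph).states
        maps = []
        for blk in self.neighbour_blocks:
            _, a = blk.attention(s, graph.adjacency)
            maps.append(a)
            s = blk(s, graph.adjacency)
        return maps


# Functional aliases matching the stage names used in the documentation.
def embed_atoms_and_bonds(graph: MolecularGraph, params: GraphEncoder
                          ) -> AtomStates:
    return params.embed(graph)


def neighbour_message_rounds(states: AtomStates, graph: MolecularGraph,
                             params: GraphEncoder, rounds: int = 3
                             ) -> AtomStates:
    return params.neighbour_rounds(states, graph, rounds)


def superatom_readout(states: AtomStates, graph: MolecularGraph,
                      params: GraphEncoder, rounds: int = 3) -> Tensor:
    return params.superatom(states, graph, rounds)
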