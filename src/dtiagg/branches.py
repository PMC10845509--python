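"""Learnable branch encoders g and h.

Each branch maps a featurized entity batch to an (n, D) embedding
matrix.  Five encoder kinds are provided:

- :class:`MLPBranch` — fully-connected stack on fixed-length descriptors
  (fingerprints, composition vectors);
- :class:`CNNBranch` — token embedding table, stacked 1-D convolutions,
  global pooling and a dense projection, for SMILES / sequence tokens;
- :class:`MPNNBranch` — message passing over molecular graphs with a
  permutation-invariant readout;
- :class:`MPNNFCBranch` — an MPNN followed by a fully-connected stack,
  which grows model capacity without deepening message passing (the
  remedy for the oversmoothing that deep message passing suffers from);
- :class:`EmbeddingBranch` — a single fully-connected layer on one-hot
  identity (implicit) vectors, i.e. a learned embedding lookup.

All weights are Glorot-uniform initialised from a seeded generator, so a
branch is a pure function of (architecture, seed, input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .featurization import MolecularGraph


class Branch:
    """Common interface: ``forward(batch) -> (n, embedding_dim) Tensor``."""

    embedding_dim: int

    def params(self) -> list[Tensor]:
        raise NotImplementedError

    def forward(self, batch) -> Tensor:
        raise NotImplementedError


def count_parameters(*objects) -> int:
    """Exact number of trainable scalars across branches/heads/models."""
    total = 0
    for obj in objects:
        for p in obj.params():
            total += p.data.size
    return total


def _dense_stack(rng, sizes: list[int]) -> list[tuple[Tensor, Tensor]]:
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = ag.parameter(ag.glorot_uniform(rng, fan_in, fan_out))
        b = ag.parameter(np.zeros(fan_out))
        layers.append((W, b))
    return layers


def _apply_stack(x: Tensor, layers, act, final_linear: bool = True) -> Tensor:
    for i, (W, b) in enumerate(layers):
        x = ag.matmul(x, W) + b
        if i < len(layers) - 1 or not final_linear:
            x = act(x)
    return x


class MLPBranch(Branch):
    """Fully-connected encoder on fixed-length real-valued descriptors.

    ``hidden`` may be empty, in which case the branch is a single linear
    map input_dim -> embedding_dim.
    """

    kind = "mlp"

    def __init__(self, input_dim: int, embedding_dim: int, hidden: list[int] = (),
                 activation: str = "relu", seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.embedding_dim = embedding_dim
        self.act = ag.activation(activation)
        self.layers = _dense_stack(rng, [input_dim, *hidden, embedding_dim])

    def params(self):
        return [w for layer in self.layers for w in layer]

    def forward(self, features) -> Tensor:
        x = features if isinstance(features, Tensor) else ag.constant(features)
        if x.shape[-1] != self.input_dim:
            raise ValueError(
                f"branch expects input width {self.input_dim}, got {x.shape[-1]}"
            )
        return _apply_stack(x, self.layers, self.act)


class EmbeddingBranch(Branch):
    """Single fully-connected layer on one-hot identity vectors.

    Forward on an index batch is exactly row selection from the weight
    table plus bias — the implicit-feature branch.
    """

    kind = "embedding_lookup"

    def __init__(self, n_entities: int, embedding_dim: int, seed: int = 0,
                 use_bias: bool = True):
        rng = np.random.default_rng(seed)
        self.n_entities = n_entities
        self.embedding_dim = embedding_dim
        self.table = ag.parameter(ag.glorot_uniform(rng, n_entities, embedding_dim))
        self.bias = ag.parameter(np.zeros(embedding_dim)) if use_bias else None

    def params(self):
        return [self.table] + ([self.bias] if self.bias is not None else [])

    def forward(self, indices) -> Tensor:
        indices = np.asarray(indices, dtype=np.intp)
        if indices.size and indices.max() >= self.n_entities:
            raise ValueError(
                f"entity index {indices.max()} out of range for table of "
                f"{self.n_entities} rows"
            )
        out = ag.gather_rows(self.table, indices)
        if self.bias is not None:
            out = out + self.bias
        return out


class CNNBranch(Branch):
    """1-D convolutional encoder for label-encoded token sequences.

    Pipeline: learned token-embedding table -> stacked valid-mode 1-D
    convolutions with nonlinearity -> global pooling over positions
    (max by default, sum optional) -> dense projection to the embedding.
    Pad tokens share index 0 in the table.
    """

    kind = "cnn"

    def __init__(self, vocab_size: int, max_len: int, embedding_dim: int,
                 token_dim: int = 16, channels: list[int] = (32, 64, 96),
                 kernel_size: int = 3, pooling: str = "max",
                 activation: str = "relu", seed: int = 0):
        receptive = 1 + len(channels) * (kernel_size - 1)
        if max_len < receptive:
            raise ValueError(
                f"max_len={max_len} shorter than receptive field {receptive}"
            )
        if pooling not in ("max", "sum"):
            raise ValueError("pooling must be 'max' or 'sum'")
        rng = np.random.default_rng(seed)
        self.vocab_size = vocab_size
        self.embedding_dim = embedding_dim
        self.pooling = pooling
        self.act = ag.activation(activation)
        # row 0 of the table is the pad embedding
        self.table = ag.parameter(ag.glorot_uniform(rng, vocab_size + 1, token_dim))
        self.convs = []
        c_in = token_dim
        for c_out in channels:
            W = ag.parameter(ag.glorot_uniform(
                rng, kernel_size * c_in, c_out, shape=(kernel_size, c_in, c_out)))
            b = ag.parameter(np.zeros(c_out))
            self.convs.append((W, b))
            c_in = c_out
        self.proj_W = ag.parameter(ag.glorot_uniform(rng, c_in, embedding_dim))
        self.proj_b = ag.parameter(np.zeros(embedding_dim))

    def params(self):
        ps = [self.table]
        for W, b in self.convs:
            ps += [W, b]
        return ps + [self.proj_W, self.proj_b]

    def forward(self, tokens) -> Tensor:
        tokens = np.asarray(tokens, dtype=np.intp)
        if tokens.ndim == 1:
            tokens = tokens[None, :]
        if tokens.max(initial=0) > self.vocab_size:
            raise ValueError("token index exceeds vocabulary size")
        n, L = tokens.shape
        x = ag.gather_rows(self.table, tokens.ravel()).reshape(n, L, -1)
        for W, b in self.convs:
            x = self.act(ag.conv1d(x, W, b))
        pooled = x.max(axis=1) if self.pooling == "max" else x.sum(axis=1)
        return ag.matmul(pooled, self.proj_W) + self.proj_b


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs for batched message passing."""
    atom_features: np.ndarray   # (N, F) over all atoms
    edge_src: np.ndarray        # (E,) directed edges (both directions per bond)
    edge_dst: np.ndarray
    edge_features: np.ndarray   # (E, B)
    graph_ids: np.ndarray       # (N,) atom -> graph index
    n_graphs: int


def batch_graphs(graphs: list[MolecularGraph]) -> GraphBatch:
    atoms, srcs, dsts, efeats, gids = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        atoms.append(g.atom_features)
        if g.n_bonds:
            b = g.bonds + offset
            srcs.extend([b[:, 0], b[:, 1]])
            dsts.extend([b[:, 1], b[:, 0]])
            efeats.extend([g.bond_features, g.bond_features])
        gids.append(np.full(g.n_atoms, gi, dtype=np.intp))
        offset += g.n_atoms
    bond_dim = graphs[0].bond_features.shape[1] if graphs else 0
    return GraphBatch(
        atom_features=np.concatenate(atoms) if atoms else np.zeros((0, 0)),
        edge_src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp),
        edge_dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp),
        edge_features=np.concatenate(efeats) if efeats else np.zeros((0, bond_dim)),
        graph_ids=np.concatenate(gids),
        n_graphs=len(graphs),
    )


class MPNNBranch(Branch):
    """Message-passing encoder over heavy-atom molecular graphs.

    T rounds of message passing: each atom receives the sum over its
    bonds of a learned linear transform of [neighbour state ; bond
    features], then updates through a learned transform with
    nonlinearity.  Readout is a permutation-invariant sum (or mean)
    over atoms, followed by a dense projection to the embedding.
    """

    kind = "mpnn"

    def __init__(self, atom_dim: int, bond_dim: int, embedding_dim: int,
                 hidden_dim: int = 32, n_rounds: int = 3, readout: str = "sum",
                 activation: str = "relu", seed: int = 0):
        if readout not in ("sum", "mean"):
            raise ValueError("readout must be 'sum' or 'mean'")
        rng = np.random.default_rng(seed)
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.n_rounds = n_rounds
        self.readout = readout
        self.act = ag.activation(activation)
        self.W_in = ag.parameter(ag.glorot_uniform(rng, atom_dim, hidden_dim))
        self.b_in = ag.parameter(np.zeros(hidden_dim))
        self.rounds = []
        for _ in range(n_rounds):
            W_msg = ag.parameter(ag.glorot_uniform(rng, hidden_dim + bond_dim, hidden_dim))
            W_self = ag.parameter(ag.glorot_uniform(rng, hidden_dim, hidden_dim))
            b = ag.parameter(np.zeros(hidden_dim))
            self.rounds.append((W_msg, W_self, b))
        self.out_W = ag.parameter(ag.glorot_uniform(rng, hidden_dim, embedding_dim))
        self.out_b = ag.parameter(np.zeros(embedding_dim))

    def params(self):
        ps = [self.W_in, self.b_in]
        for W_msg, W_self, b in self.rounds:
            ps += [W_msg, W_self, b]
        return ps + [self.out_W, self.out_b]

    def node_states(self, batch: GraphBatch) -> Tensor:
        h = self.act(ag.matmul(ag.constant(batch.atom_features), self.W_in) + self.b_in)
        n_atoms = batch.atom_features.shape[0]
        efeat = ag.constant(batch.edge_features)
        for W_msg, W_self, b in self.rounds:
            if batch.edge_src.size:
                src_h = ag.gather_rows(h, batch.edge_src)
                msg_in = ag.concat([src_h, efeat], axis=1)
                messages = ag.matmul(msg_in, W_msg)
                agg = ag.segment_sum(messages, batch.edge_dst, n_atoms)
                h = self.act(ag.matmul(h, W_self) + agg + b)
            else:
                h = self.act(ag.matmul(h, W_self) + b)
        return h

    def forward(self, batch: GraphBatch) -> Tensor:
        h = self.node_states(batch)
        pooled = ag.segment_sum(h, batch.graph_ids, batch.n_graphs)
        if self.readout == "mean":
            counts = np.bincount(batch.graph_ids, minlength=batch.n_graphs)
            pooled = pooled * (1.0 / counts)[:, None]
        return ag.matmul(pooled, self.out_W) + self.out_b


class MPNNFCBranch(Branch):
    """MPNN followed by a fully-connected stack before aggregation.

    The FC stack raises branch capacity while message-passing depth
    stays shallow, avoiding oversmoothing.  An empty ``fc_hidden`` with
    matching dims reduces exactly to the bare MPNN.
    """

    kind = "mpnn_fc"

    def __init__(self, atom_dim: int, bond_dim: int, embedding_dim: int,
                 hidden_dim: int = 32, n_rounds: int = 2,
                 fc_hidden: list[int] = (64,), readout: str = "sum",
                 activation: str = "relu", seed: int = 0):
        rng = np.random.default_rng(seed + 104729)
        self.mpnn = MPNNBranch(atom_dim, bond_dim,
                               embedding_dim=embedding_dim if not fc_hidden else fc_hidden[0],
                               hidden_dim=hidden_dim, n_rounds=n_rounds,
                               readout=readout, activation=activation, seed=seed)
        self.embedding_dim = embedding_dim
        self.act = ag.activation(activation)
        if fc_hidden:
            self.fc = _dense_stack(rng, [*fc_hidden, embedding_dim])
        else:
            self.fc = []

    def params(self):
        return self.mpnn.params() + [w for layer in self.fc for w in layer]

    def forward(self, batch: GraphBatch) -> Tensor:
        x = self.mpnn.forward(batch)
        if self.fc:
            x = self.act(x)
            x = _apply_stack(x, self.fc, self.act)
        return x
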