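"""Embedding-aggregation heads and the composed two-branch predictor.

Three interchangeable heads combine a compound embedding g(x) in R^D1
and a protein embedding h(t) in R^D2 into a scalar affinity prediction:

- dot product      f = sum_d g_d h_d            (parameter-free; D1 == D2)
- MLP              f = MLP([g ; h])             (concatenate, dense stack, 1 output)
- tensor product   f = sum_k sum_l w_kl g_k h_l (bilinear form g' W h)

The tensor head is evaluated as the matrix-vector form g' W h rather
than materializing the outer product; the two are numerically equal.
A hybrid branch combines explicit and implicit per-entity embeddings
through an internal MLP before the external head sees them.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .branches import Branch, EmbeddingBranch, _apply_stack, _dense_stack


class ConfigurationError(ValueError):
    """Raised when head and branch dimensionalities are inconsistent."""


# ---------------------------------------------------------------------------
# scalar operations (vector in, scalar out)
# ---------------------------------------------------------------------------

def dot_aggregate(g, h) -> float:
    """Dot product of the two embeddings, used directly as the prediction."""
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape:
        raise ConfigurationError(
            f"dot aggregation requires equal embedding sizes, got {g.shape} vs {h.shape}"
        )
    return float(g @ h)


def tensor_aggregate(g, h, W, bias: float = 0.0) -> float:
    """Bilinear form sum_k sum_l w_kl g_k h_l (+ optional bias)."""
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape != (g.size, h.size):
        raise ConfigurationError(
            f"tensor head weight shape {W.shape} does not match ({g.size}, {h.size})"
        )
    return float(g @ W @ h + bias)


def mlp_aggregate(g, h, head: "MLPHead") -> float:
    """Scalar output of the head's dense stack on the concatenation [g, h]."""
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.size + h.size != head.input_dim:
        raise ConfigurationError(
            f"MLP head expects input width {head.input_dim}, got {g.size + h.size}"
        )
    out = head.forward(ag.constant(g[None, :]), ag.constant(h[None, :]))
    return float(out.data[0])


# ---------------------------------------------------------------------------
# head classes (batched)
# ---------------------------------------------------------------------------

class Head:
    name: str

    def params(self) -> list[Tensor]:
        return []

    def forward(self, g: Tensor, h: Tensor) -> Tensor:
        """(n, D1), (n, D2) -> (n,) predictions."""
        raise NotImplementedError


class DotHead(Head):
    """Parameter-free dot-product head; requires D1 == D2."""

    name = "dot"

    def __init__(self, d1: int, d2: int):
        if d1 != d2:
            raise ConfigurationError(
                f"dot head requires equal embedding dims, got D1={d1}, D2={d2}"
            )

    def forward(self, g, h):
        return (g * h).sum(axis=1)


class MLPHead(Head):
    """Dense stack on [g ; h] terminating at a single output node.

    ``hidden=[L]`` is the canonical single-hidden-layer head; several
    hidden layers are allowed.
    """

    name = "mlp"

    def __init__(self, d1: int, d2: int, hidden: list[int] = (64,),
                 activation: str = "relu", seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_dim = d1 + d2
        self.hidden = list(hidden)
        self.act = ag.activation(activation)
        self.layers = _dense_stack(rng, [self.input_dim, *self.hidden, 1])

    def params(self):
        return [w for layer in self.layers for w in layer]

    def forward(self, g, h):
        x = ag.concat([g, h], axis=1)
        out = _apply_stack(x, self.layers, self.act)
        return out.reshape(-1)

    def hidden_activations(self, g, h) -> list[Tensor]:
        """Post-activation values of each hidden layer, for embedding extraction."""
        x = ag.concat([g, h], axis=1)
        acts = []
        for W, b in self.layers[:-1]:
            x = self.act(ag.matmul(x, W) + b)
            acts.append(x)
        return acts


class TensorHead(Head):
    """Bilinear head with learnable W in R^{D1 x D2}; bias off by default."""

    name = "tensor"

    def __init__(self, d1: int, d2: int, use_bias: bool = False, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = ag.parameter(ag.glorot_uniform(rng, d1, d2))
        self.bias = ag.parameter(np.zeros(1)) if use_bias else None

    def params(self):
        return [self.W] + ([self.bias] if self.bias is not None else [])

    def forward(self, g, h):
        out = (ag.matmul(g, self.W) * h).sum(axis=1)
        if self.bias is not None:
            out = out + self.bias.reshape(())
        return out


def make_head(name: str, d1: int, d2: int, **kwargs) -> Head:
    if name == "dot":
        return DotHead(d1, d2)
    if name == "mlp":
        return MLPHead(d1, d2, **kwargs)
    if name == "tensor":
        return TensorHead(d1, d2, **kwargs)
    raise ConfigurationError(f"unknown aggregation strategy {name!r}")


# ---------------------------------------------------------------------------
# hybrid explicit+implicit branch
# ---------------------------------------------------------------------------

class HybridBranch(Branch):
    """Entity encoder combining explicit and implicit embeddings.

    The intermediate embeddings from the explicit branch and the
    implicit (embedding-lookup) branch are concatenated and passed
    through an internal dense stack, yielding a vector embedding that
    the external aggregation head consumes.
    """

    kind = "hybrid"

    def __init__(self, explicit_branch: Branch, n_entities: int,
                 implicit_dim: int, embedding_dim: int,
                 internal_hidden: list[int] = (32,),
                 activation: str = "relu", seed: int = 0):
        rng = np.random.default_rng(seed + 15485863)
        self.explicit = explicit_branch
        self.implicit = EmbeddingBranch(n_entities, implicit_dim, seed=seed + 1)
        self.embedding_dim = embedding_dim
        self.act = ag.activation(activation)
        in_dim = explicit_branch.embedding_dim + implicit_dim
        self.internal = _dense_stack(rng, [in_dim, *internal_hidden, embedding_dim])

    def params(self):
        ps = self.explicit.params() + self.implicit.params()
        return ps + [w for layer in self.internal for w in layer]

    def forward(self, batch) -> Tensor:
        explicit_input, indices = batch
        e = self.explicit.forward(explicit_input)
        i = self.implicit.forward(indices)
        return hybrid_entity_embedding(e, i, self.internal, self.act)


def hybrid_entity_embedding(explicit_emb: Tensor, implicit_emb: Tensor,
                            internal_stack, act) -> Tensor:
    """Concatenate explicit and implicit embeddings and run the internal MLP."""
    x = ag.concat([explicit_emb, implicit_emb], axis=1)
    return _apply_stack(x, internal_stack, act)


# ---------------------------------------------------------------------------
# composed predictor
# ---------------------------------------------------------------------------

class TwoBranchModel:
    """f(x, t) = head(g(x), h(t)) with entity-level batched evaluation.

    ``compound_inputs`` / ``protein_inputs`` are whatever the respective
    branch kinds consume (descriptor matrices, token matrices, graph
    batches, index arrays, or (explicit, indices) tuples for hybrid
    branches); pair predictions gather embedding rows by entity index.
    """

    def __init__(self, compound_branch: Branch, protein_branch: Branch, head: Head):
        self.compound_branch = compound_branch
        self.protein_branch = protein_branch
        self.head = head

    def params(self):
        return (self.compound_branch.params() + self.protein_branch.params()
                + self.head.params())

    def embed(self, compound_inputs, protein_inputs) -> tuple[Tensor, Tensor]:
        return (self.compound_branch.forward(compound_inputs),
                self.protein_branch.forward(protein_inputs))

    def forward_pairs(self, compound_inputs, protein_inputs,
                      c_idx, p_idx) -> Tensor:
        G, H = self.embed(compound_inputs, protein_inputs)
        g = ag.gather_rows(G, np.asarray(c_idx, dtype=np.intp))
        h = ag.gather_rows(H, np.asarray(p_idx, dtype=np.intp))
        return self.head.forward(g, h)

    def predict(self, compound_inputs, protein_inputs, c_idx, p_idx) -> np.ndarray:
        """Numpy predictions without gradient side effects."""
        return self.forward_pairs(compound_inputs, protein_inputs,
                                  c_idx, p_idx).data.copy()
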