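"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's branch encoders and aggregation heads are small neural
networks trained with gradient descent.  This module supplies the tape:
a :class:`Tensor` wrapping an ``ndarray``, a handful of differentiable
operations (affine maps, elementwise nonlinearities, gather/segment-sum
for graph message passing, a 1-D convolution), and an Adam optimizer.

Only the operations the model zoo needs are implemented; gradients are
accumulated by topological traversal of the recorded graph.  Everything
is CPU NumPy and fully deterministic given seeded initial weights.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "matmul",
    "concat",
    "gather_rows",
    "segment_sum",
    "conv1d",
    "relu",
    "tanh",
    "activation",
    "glorot_uniform",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    ``requires_grad`` tensors accumulate gradients in ``.grad`` when
    :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph construction helpers -----------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        needs = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=needs,
                      parents=parents if needs else (),
                      backward=backward if needs else None)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, out):
            if self.requires_grad:
                self._accum(-grad)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(grad, out):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out_data = self.data ** exponent

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad, out):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis: int):
        """Maximum along ``axis``; gradient flows to the (first) argmax."""
        out_data = self.data.max(axis=axis)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(grad, out):
            if not self.requires_grad:
                return
            g = np.zeros_like(self.data)
            np.put_along_axis(g, argmax, np.expand_dims(grad, axis), axis)
            self._accum(g)

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape):
        src_shape = self.shape
        out_data = self.data.reshape(*shape)

        def backward(grad, out):
            if self.requires_grad:
                self._accum(grad.reshape(src_shape))

        return self._make(out_data, (self,), backward)

    # -- backward pass -------------------------------------------------------
    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor"):
            stack = [(node, iter(node._parents))]
            if id(node) in seen:
                return
            seen.add(id(node))
            while stack:
                current, parents = stack[-1]
                advanced = False
                for p in parents:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(current)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad, node)


def parameter(data, requires_grad: bool = True) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=requires_grad)


def constant(data) -> Tensor:
    return Tensor(data)


# ---------------------------------------------------------------------------
# free-function ops
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    out_data = a.data @ b.data

    def backward(grad, out):
        if a.requires_grad:
            ga = grad @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ grad
            b._accum(_unbroadcast(gb, b.shape))

    return a._make(out_data, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(grad[tuple(idx)])

    return tensors[0]._make(out_data, tuple(tensors), backward)


def gather_rows(x: Tensor, indices) -> Tensor:
    """Select rows ``x[indices]`` along axis 0; scatter-adds on backward."""
    indices = np.asarray(indices, dtype=np.intp)
    out_data = x.data[indices]

    def backward(grad, out):
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, indices, grad)
            x._accum(g)

    return x._make(out_data, (x,), backward)


def segment_sum(x: Tensor, segment_ids, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets (graph readout)."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, x.data)

    def backward(grad, out):
        if x.requires_grad:
            x._accum(grad[segment_ids])

    return x._make(out_data, (x,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Valid-mode 1-D convolution.

    ``x``: (n, L, C_in); ``weight``: (K, C_in, C_out); output (n, L-K+1, C_out).
    """
    K = weight.data.shape[0]
    L = x.data.shape[1]
    if L < K:
        raise ValueError(f"sequence length {L} shorter than kernel width {K}")
    L_out = L - K + 1
    out_data = np.zeros((x.data.shape[0], L_out, weight.data.shape[2]))
    for k in range(K):
        out_data += x.data[:, k:k + L_out, :] @ weight.data[k]
    if bias is not None:
        out_data += bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(grad, out):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for k in range(K):
                gx[:, k:k + L_out, :] += grad @ weight.data[k].T
            x._accum(gx)
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            for k in range(K):
                gw[k] = np.einsum("nlc,nld->cd", x.data[:, k:k + L_out, :], grad)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(grad.sum(axis=(0, 1)))

    return x._make(out_data, parents, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(grad, out):
        if x.requires_grad:
            x._accum(grad * mask)

    return x._make(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(grad, out):
        if x.requires_grad:
            x._accum(grad * (1.0 - out_data ** 2))

    return x._make(out_data, (x,), backward)


_ACTIVATIONS = {
    "relu": relu,
    "tanh": tanh,
    "linear": lambda x: x,
    "identity": lambda x: x,
}


def activation(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam with bias-corrected moments and decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
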