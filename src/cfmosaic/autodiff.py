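"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for attention-based message passing on a sample
graph: dense matmul, broadcast add/mul, elementwise nonlinearities,
row gather and segment (scatter-add) reductions, and reductions to a
scalar loss.  Gradients are accumulated by a topologically ordered
backward sweep; correctness is checked against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- helpers -------------------------------------------------------

    def _unary(self, out_data, grad_fn):
        out = Tensor(out_data, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self.grad += grad_fn(g)

        out._backward = backward if out.requires_grad else None
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _binary(a: Tensor, b: Tensor, data, da, db) -> Tensor:
    req = a.requires_grad or b.requires_grad
    out = Tensor(data, req, (a, b))

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(da(g), a.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(db(g), b.shape)

    out._backward = backward if req else None
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(
        a, b, a.data / b.data,
        lambda g: g / b.data,
        lambda g: -g * a.data / (b.data ** 2),
    )


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(
        a, b, a.data @ b.data,
        lambda g: g @ b.data.T,
        lambda g: a.data.T @ g,
    )


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)
    return a._unary(out_data, lambda g: g * out_data)


def log(a) -> Tensor:
    a = _as_tensor(a)
    return a._unary(np.log(a.data), lambda g: g / a.data)


def pow_const(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    return a._unary(
        a.data ** exponent, lambda g: g * exponent * a.data ** (exponent - 1.0)
    )


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    factor = np.where(a.data > 0, 1.0, slope)
    return a._unary(a.data * factor, lambda g: g * factor)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _as_tensor(a)
    neg = a.data <= 0
    out_data = np.where(neg, alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0), a.data)
    local = np.where(neg, out_data + alpha, 1.0)
    return a._unary(out_data, lambda g: g * local)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    return a._unary(s, lambda g: g * s * (1.0 - s))


def gather(a, index) -> Tensor:
    """Row gather: out[i] = a[index[i]]."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=int)

    def grad_fn(g):
        out = np.zeros_like(a.data)
        np.add.at(out, index, g)
        return out

    return a._unary(a.data[index], grad_fn)


def segment_sum(a, segment_ids, num_segments: int) -> Tensor:
    """Scatter-add rows of ``a`` into ``num_segments`` output rows."""
    a = _as_tensor(a)
    segment_ids = np.asarray(segment_ids, dtype=int)
    out_shape = (num_segments,) + a.data.shape[1:]
    data = np.zeros(out_shape)
    np.add.at(data, segment_ids, a.data)
    return a._unary(data, lambda g: g[segment_ids])


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    out._backward = backward if req else None
    return out


def row_sum(a) -> Tensor:
    """Sum over axis 1, keepdims."""
    a = _as_tensor(a)
    return a._unary(
        a.data.sum(axis=1, keepdims=True),
        lambda g: np.broadcast_to(g, a.data.shape).copy(),
    )


def mean_all(a) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size
    return a._unary(
        np.array(a.data.mean()), lambda g: np.full(a.data.shape, float(g) / n)
    )


def sum_all(a) -> Tensor:
    a = _as_tensor(a)
    return a._unary(np.array(a.data.sum()), lambda g: np.full(a.data.shape, float(g)))


def softmax_rows(logits: Tensor) -> Tensor:
    """Row-wise softmax (shift by the constant row max for stability)."""
    shift = sub(logits, logits.data.max(axis=1, keepdims=True))
    e = exp(shift)
    return div(e, row_sum(e))


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1 ** self.t)
            v_hat = v / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
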