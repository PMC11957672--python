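"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph networks need: dense linear
algebra, elementwise nonlinearities, row gather/scatter for edge-list
message passing, concatenation and reductions. Gradients are accumulated
on leaf tensors by :meth:`Tensor.backward` via a topological sweep of the
recorded tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "sub",
    "mul",
    "div",
    "matmul",
    "relu",
    "leaky_relu",
    "sigmoid",
    "softplus",
    "exp",
    "concat",
    "gather_rows",
    "scatter_sum",
    "sum_all",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __rmul__(self, other):
        return mul(other, self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def tensor(value, requires_grad: bool = False) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value, requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _binary(a: Tensor, b: Tensor, value, back_a, back_b) -> Tensor:
    out = Tensor(value)
    out.requires_grad = a.requires_grad or b.requires_grad
    if out.requires_grad:
        out._parents = (a, b)

        def _bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(back_a(g), a.value.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(back_b(g), b.value.shape))

        out._backward = _bw
    return out


def _unary(a: Tensor, value, back) -> Tensor:
    out = Tensor(value)
    out.requires_grad = a.requires_grad
    if out.requires_grad:
        out._parents = (a,)

        def _bw(g):
            a._accumulate(back(g))

        out._backward = _bw
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.value + b.value, lambda g: g, lambda g: g)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.value - b.value, lambda g: g, lambda g: -g)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.value * b.value, lambda g: g * b.value, lambda g: g * a.value)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(
        a,
        b,
        a.value / b.value,
        lambda g: g / b.value,
        lambda g: -g * a.value / (b.value**2),
    )


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(
        a,
        b,
        a.value @ b.value,
        lambda g: g @ b.value.T,
        lambda g: a.value.T @ g,
    )


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.value > 0
    return _unary(a, np.where(mask, a.value, 0.0), lambda g: g * mask)


def leaky_relu(a, negative_slope: float = 0.01) -> Tensor:
    a = _as_tensor(a)
    mask = a.value > 0
    slope = np.where(mask, 1.0, negative_slope)
    return _unary(a, a.value * slope, lambda g: g * slope)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.value, -500, 500)))
    return _unary(a, s, lambda g: g * s * (1.0 - s))


def softplus(a) -> Tensor:
    """log(1 + e^x), computed stably; derivative is the logistic function."""
    a = _as_tensor(a)
    val = np.logaddexp(0.0, a.value)
    sig = 1.0 / (1.0 + np.exp(-np.clip(a.value, -500, 500)))
    return _unary(a, val, lambda g: g * sig)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    e = np.exp(np.clip(a.value, -700, 700))
    return _unary(a, e, lambda g: g * e)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.value.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = _bw
    return out


def gather_rows(a, index: np.ndarray) -> Tensor:
    """Select rows ``a[index]``; the adjoint scatter-adds back."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=np.intp)

    def back(g):
        out = np.zeros_like(a.value)
        np.add.at(out, index, g)
        return out

    return _unary(a, a.value[index], back)


def scatter_sum(a, index: np.ndarray, n: int) -> Tensor:
    """Sum rows of ``a`` into ``n`` bins given by ``index``; adjoint gathers."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=np.intp)
    out_val = np.zeros((n,) + a.value.shape[1:], dtype=np.float64)
    np.add.at(out_val, index, a.value)
    return _unary(a, out_val, lambda g: g[index])


def sum_all(a) -> Tensor:
    a = _as_tensor(a)
    return _unary(a, np.array(a.value.sum()), lambda g: np.full_like(a.value, float(g)))
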