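"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations needed by the graph models and losses are implemented:
broadcasted arithmetic, matmul, reductions, elementwise nonlinearities,
row gather and segment-sum (the scatter/gather pair used for message
passing), and concatenation. Gradients are accumulated in float64.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make ndarray <op> Tensor defer to the reflected Tensor methods
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- infrastructure ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
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
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def backward(g):
            self._accum(g)
            other._accum(g)

        out._backward = backward
        return out

    def __radd__(self, other) -> "Tensor":
        return self.__add__(other)

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self.__add__(-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return (-self).__add__(other)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = backward
        return out

    def __rmul__(self, other) -> "Tensor":
        return self.__mul__(other)

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, self._needs(other), (self, other))

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        out._backward = backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other).__truediv__(self)

    def __pow__(self, exponent: float) -> "Tensor":
        """Elementwise power with a scalar exponent; 0**0 == 1 and the
        gradient is zeroed where the base is 0 (subgradient convention)."""
        e = float(exponent)
        out = Tensor(np.power(self.data, e), self.requires_grad, (self,))

        def backward(g):
            if e == 0.0:
                self._accum(np.zeros_like(self.data))
                return
            safe = np.where(self.data != 0.0,
                            e * np.power(np.where(self.data != 0.0, self.data, 1.0), e - 1.0),
                            0.0)
            self._accum(g * safe)

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, self._needs(other), (self, other))

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = backward
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities --------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def sqrt(self) -> "Tensor":
        return self.__pow__(0.5)

    def clamp(self, lo: float | None = None, hi: float | None = None) -> "Tensor":
        clipped = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            inside &= self.data >= lo
        if hi is not None:
            inside &= self.data <= hi
        out = Tensor(clipped, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * inside)
        return out

    # -- gather / scatter -------------------------------------------------

    def take(self, indices) -> "Tensor":
        """Gather rows (axis 0). Backward scatter-adds into the source."""
        idx = np.asarray(indices, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = backward
        return out

    def segment_sum(self, segment_ids, num_segments: int) -> "Tensor":
        """Sum rows into `num_segments` buckets given per-row bucket ids."""
        ids = np.asarray(segment_ids, dtype=np.intp)
        shape = (num_segments,) + self.data.shape[1:]
        acc = np.zeros(shape, dtype=np.float64)
        np.add.at(acc, ids, self.data)
        out = Tensor(acc, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(np.asarray(g)[ids])
        return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out._backward = backward
    return out
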