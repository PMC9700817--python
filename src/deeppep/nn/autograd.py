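"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operator set the model architectures need: broadcast
arithmetic, batched matmul, element-wise nonlinearities, reductions,
reshaping/concatenation, fancy-index gathers (embeddings, sequence
reversal) and a numerically stable softmax.  Gradients flow through a tape
of closures; :func:`Tensor.backward` runs the tape in reverse topological
order.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(_as_array(other)) + (-self)

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(data, (self,), backward)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / _as_array(other))

    def __rtruediv__(self, other):
        return Tensor(_as_array(other)) * self ** -1.0

    def matmul(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data)

        return self._make(data, (self,), backward)

    def log(self):
        data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(data, (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - data * data))

        return self._make(data, (self,), backward)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return self._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)
        data = np.abs(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(data, (self,), backward)

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        data = np.swapaxes(self.data, a, b)

        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return self._make(data, (self,), backward)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, idx, g)
                self._accum(grad)

        return self._make(data, (self,), backward)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather leading-axis rows (embedding lookup); any index shape."""
        indices = np.asarray(indices)
        data = self.data[indices]

        def backward(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, indices, g)
                self._accum(grad)

        return self._make(data, (self,), backward)

    @staticmethod
    def cat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [
            t if isinstance(t, Tensor) else Tensor(_as_array(t)) for t in tensors
        ]
        data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out = Tensor(data)
        if any(t.requires_grad for t in tensors):
            out.requires_grad = True
            out._prev = tuple(tensors)
            out._backward = backward
        return out

    @staticmethod
    def stack(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        expanded = []
        for t in tensors:
            shape = list(t.shape)
            shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
            expanded.append(t.reshape(*shape))
        return Tensor.cat(expanded, axis=axis)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backward pass -----------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
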