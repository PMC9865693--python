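"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: every operation on :class:`Tensor` records its
parents and a closure that propagates the output gradient back to them.
``Tensor.backward()`` runs the closures in reverse topological order.

The engine is dtype-agnostic (it keeps whatever float dtype the inputs
carry), which lets unit tests run recurrences in float64 while networks
train in float32.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64)
                                                  if not isinstance(x, np.ndarray) else x)


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None if node._parents else node.grad

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        out._backward = backward
        return out

    # -- elementwise functions ------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        out = Tensor(np.sqrt(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / out.data)
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        x = self.data
        val = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, None, 500))),
                       np.exp(np.clip(x, -500, None)) /
                       (1.0 + np.exp(np.clip(x, -500, None))))
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through only inside the range."""
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        mask = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(self.dtype))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(self.dtype))
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max of the underlying data with no gradient (for stable softmax)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape manipulation ---------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = backward
        return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [(_as_tensor(t)) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = backward
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [(_as_tensor(t)) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))
    out._backward = backward
    return out
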