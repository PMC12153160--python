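"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model layers (gated recurrent encoder, multi-head cross-attention,
link attention) are expressed as compositions of the ``Tensor`` operations
defined here.  Gradients are exact reverse-mode derivatives; the test suite
verifies them against central finite differences.

Design notes
------------
* Every op records its parents and a closure that accumulates gradients.
  ``Tensor.backward`` runs a topological sort and applies the closures.
* Broadcasting follows NumPy semantics; ``_unbroadcast`` sums gradients
  over broadcast axes so shapes always match the leaf.
* ``max`` routes the gradient to the first maximal element along the axis
  (a valid subgradient at ties).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph machinery -----------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not (t.requires_grad or t._parents):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _child(self, data, parents, backward) -> "Tensor":
        rg = any(p.requires_grad or p._parents for p in parents)
        return Tensor(data, requires_grad=False, _parents=parents if rg else (),
                      _backward=backward if rg else None)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._child(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._child(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._child(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._child(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        return self._child(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._child(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._child(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._child(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._child(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._child(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._child(self.data * mask, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._child(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(*inv))

        return self._child(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        return self._child(self.data[idx], (self,), backward)

    def gather_time(self, index: np.ndarray):
        """out[b, t] = self[b, index[b, t]] for a (B, T, D) tensor.

        Used to reverse each padded sequence within its own length.
        """
        b_idx = np.arange(self.shape[0])[:, None]

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, (b_idx, index), g)
            self._accum(acc)

        return self._child(self.data[b_idx, index], (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        return self._child(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        # subgradient: route to first argmax along `axis`
        amax = np.expand_dims(self.data.argmax(axis=axis), axis)
        onehot = np.zeros_like(self.data)
        np.put_along_axis(onehot, amax, 1.0, axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(onehot * g)

        return self._child(out_data, (self,), backward)

    # -- composite, numerically stable ----------------------------------------
    def softmax(self, axis: int = -1):
        """Row-stable softmax along `axis` (max-shift is treated as constant)."""
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        z = self - shift
        return z - z.exp().sum(axis=axis, keepdims=True).log()


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    rg = any(t.requires_grad or t._parents for t in tensors)
    return Tensor(out_data, _parents=tuple(tensors) if rg else (),
                  _backward=backward if rg else None)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    rg = any(t.requires_grad or t._parents for t in tensors)
    return Tensor(out_data, _parents=tuple(tensors) if rg else (),
                  _backward=backward if rg else None)
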