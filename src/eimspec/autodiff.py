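"""Compact reverse-mode automatic differentiation over NumPy arrays.

The engine implements exactly the operator set the spectrum-prediction model
needs: broadcasting arithmetic, (batched) matrix products, the usual neural
nonlinearities, reductions, stable log-sum-exp, and the gather/scatter
primitives required for sparse graph batching (``gather_rows``,
``segment_sum``) and per-sample index reversal (``take_per_row``).

Gradients are accumulated by a topological sweep over the tape.  All tensors
are float64; the engine is fully deterministic (no threading, no atomics
beyond ``np.add.at``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "logsumexp",
    "matmul",
    "maximum",
    "relu",
    "segment_sum",
    "sigmoid",
    "softplus",
    "take_per_row",
    "tanh",
    "where_mask",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus tape bookkeeping for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old_shape),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:
                node.grad = g if node.grad is None else node.grad + g
        # leaves reached through the loop above already stored their grad;
        # handle the degenerate case where self is itself a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


# -- free functions ----------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.ndim == 1:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2)) if b.ndim > 1 else g * b.data
            ga = _unbroadcast(ga, a.shape)
        else:
            gb_side = b.data if b.ndim > 1 else b.data[:, None]
            gg = g if b.ndim > 1 else g[..., None]
            ga = np.matmul(gg, np.swapaxes(gb_side, -1, -2))
            ga = _unbroadcast(ga, a.shape)
        if b.ndim == 1:
            if a.ndim == 1:
                gb = g * a.data
            else:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g[..., None])[..., 0]
                gb = _unbroadcast(gb, b.shape)
        else:
            ga_side = a.data if a.ndim > 1 else a.data[None, :]
            gg = g if a.ndim > 1 else g[None, :]
            gb = np.matmul(np.swapaxes(ga_side, -1, -2), gg)
            gb = _unbroadcast(gb, b.shape)
        return (ga, gb)

    return Tensor._from_op(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    mask = x.data > 0
    return Tensor._from_op(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def maximum(x: Tensor, value: float) -> Tensor:
    """Elementwise max with a constant; gradient passes where ``x > value``."""
    x = Tensor._lift(x)
    mask = x.data > value
    return Tensor._from_op(np.where(mask, x.data, value), (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor._from_op(
        out_data, (x,), lambda g: (g * out_data * (1.0 - out_data),)
    )


def tanh(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out_data = np.tanh(x.data)
    return Tensor._from_op(out_data, (x,), lambda g: (g * (1.0 - out_data**2),))


def softplus(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out_data = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor._from_op(out_data, (x,), lambda g: (g * sig,))


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    x = Tensor._lift(x)
    m = x.data.max(axis=axis, keepdims=True)
    out_data = np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True)) + m
    soft = np.exp(x.data - out_data)
    if not keepdims:
        out_squeezed = np.squeeze(out_data, axis=axis)
    else:
        out_squeezed = out_data

    def backward(g):
        g_exp = g if keepdims else np.expand_dims(g, axis)
        return (g_exp * soft,)

    return Tensor._from_op(out_squeezed, (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """``y[i] = x[index[i]]`` along axis 0 (graph-batch edge gather)."""
    x = Tensor._lift(x)
    index = np.asarray(index, dtype=np.intp)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, index, g)
        return (gx,)

    return Tensor._from_op(x.data[index], (x,), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets (permutation invariant)."""
    x = Tensor._lift(x)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, x.data)
    return Tensor._from_op(out_data, (x,), lambda g: (g[segment_ids],))


def take_per_row(x: Tensor, index: np.ndarray) -> Tensor:
    """``y[i, k] = x[i, index[i, k]]`` — per-sample column gather (B×D)."""
    x = Tensor._lift(x)
    index = np.asarray(index, dtype=np.intp)
    rows = np.arange(x.data.shape[0])[:, None]

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (rows, index), g)
        return (gx,)

    return Tensor._from_op(x.data[rows, index], (x,), backward)


def where_mask(mask: np.ndarray, x: Tensor, other: float = 0.0) -> Tensor:
    """Select ``x`` where a constant boolean mask holds, else ``other``."""
    x = Tensor._lift(x)
    mask = np.asarray(mask, dtype=bool)
    return Tensor._from_op(
        np.where(mask, x.data, other), (x,), lambda g: (g * mask,)
    )
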