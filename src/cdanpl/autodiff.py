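"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd style, sized for the 1-D spectral
networks in this package: dense layers, 1-D convolution, self-attention,
layer normalization and the loss arithmetic all compose from the primitives
here.  Every :class:`Tensor` holds a numpy array, an accumulated gradient of
the same shape, and a closure that propagates gradients to its parents.

Design constraints:

* gradients are accumulated (``+=``), so a tensor used twice receives the sum
  of both contributions;
* broadcasting follows numpy semantics, with gradients summed back to the
  original shape (:func:`_unbroadcast`);
* the graph is retained until :meth:`Tensor.backward` finishes, which lets
  callers read gradients of *intermediate* tensors (needed for Grad-CAM).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = True):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping -------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data**p, (self,), None)
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                return (g @ b.T, a.T @ g)
            # batched matmul (..., m, k) @ (..., k, n)
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = self._make(val, (self,), None)
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = self._make(val, (self,), None)
        out._backward = lambda g: (g * 0.5 / val,)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = self._make(val, (self,), None)
        out._backward = lambda g: (g * (1.0 - val**2),)
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        val = 0.5 * (np.tanh(0.5 * self.data) + 1.0)  # numerically stable
        out = self._make(val, (self,), None)
        out._backward = lambda g: (g * val * (1.0 - val),)
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        out = self._make(np.clip(self.data, lo, hi), (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == val).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
        squeezed = val if keepdims or axis is None else np.squeeze(val, axis)
        if axis is None and not keepdims:
            squeezed = self.data.max()
        out = self._make(squeezed, (self,), None)

        def backward(g):
            g2 = g if (keepdims or axis is None) else np.expand_dims(g, axis)
            return (mask * g2,)

        out._backward = backward
        return out

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)
        simple = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx)
        )

        def backward(g):
            full = np.zeros_like(self.data)
            if simple:  # no duplicate positions: direct assignment
                full[idx] = g
            else:
                np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # -- fused ops (single tape node with analytic backward) ---------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = self._make(p, (self,), None)

        def backward(g):
            s = (g * p).sum(axis=axis, keepdims=True)
            return (p * (g - s),)

        out._backward = backward
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        val = z - lse
        out = self._make(val, (self,), None)

        def backward(g):
            return (g - np.exp(val) * g.sum(axis=axis, keepdims=True),)

        out._backward = backward
        return out

    # -- autograd ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only on scalars")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        # `owned` marks gradients this pass may mutate in place; gradients
        # adopted directly from a backward closure are copy-on-write, since
        # a closure may hand the same buffer to several parents
        owned: dict[int, bool] = {}
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g
                    owned[id(parent)] = False
                elif owned.get(id(parent), True):
                    parent.grad += g
                else:
                    parent.grad = parent.grad + g
                    owned[id(parent)] = True


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = tensors[0]._make(data, tuple(tensors), None)
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = tensors[0]._make(data, tuple(tensors), None)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0)[i] for i in range(len(tensors)))

    out._backward = backward
    return out
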