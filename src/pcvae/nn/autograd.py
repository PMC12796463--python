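"""Minimal reverse-mode automatic differentiation on numpy arrays.

The PC-VAE needs gradients through shared-weight MLPs, batch normalization,
multi-head attention and a Chamfer reconstruction loss. This module provides a
small define-by-run tape: each operation returns a :class:`Tensor` holding the
numpy result and a closure that routes upstream gradients to its parents.
``Tensor.backward()`` runs the closures in reverse topological order.

Only the operations the model uses are implemented. Arrays keep their dtype;
the network itself runs in float32, while gradient-check tests can build
float64 graphs.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "add", "sub", "mul", "neg", "matmul", "power",
    "relu", "tanh", "exp", "log",
    "tsum", "tmean", "reshape", "transpose", "concatenate",
    "broadcast_to", "softmax", "take_row", "segment_mean", "chamfer_to_fixed",
]


def _as_array(x):
    if isinstance(x, Tensor):
        raise TypeError("expected a plain array, got Tensor")
    return np.asarray(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting expanded to reach it."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 stretched by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operators
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return add(neg(self), other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, k):
        return power(self, k)

    # -- backward pass -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        # topological order over the reachable graph
        topo, seen = [], set()
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
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))

        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


class Parameter(Tensor):
    """Trainable tensor (float32 by default)."""

    __slots__ = ()

    def __init__(self, data, dtype=np.float32):
        super().__init__(np.asarray(data, dtype=dtype), requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _coerce(a, b) -> tuple[Tensor, Tensor]:
    """Wrap plain operands, matching the dtype of the Tensor operand so python
    scalars do not upcast a float32 graph to float64."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor):
        return a, Tensor(np.asarray(b, dtype=a.data.dtype))
    if isinstance(b, Tensor) and not isinstance(a, Tensor):
        return Tensor(np.asarray(a, dtype=b.data.dtype)), b
    return _wrap(a), _wrap(b)


def _needs_grad(*tensors) -> bool:
    return any(t.requires_grad for t in tensors)


_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference): no parents are retained, so
    intermediate arrays are freed as soon as they go out of scope."""
    global _grad_enabled
    previous = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = previous


def _make(data, parents, backward, requires_grad):
    requires_grad = requires_grad and _grad_enabled
    out = Tensor(data, requires_grad=requires_grad)
    if requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    # grads are only ever rebound (never mutated in place), so storing a view
    # of an upstream gradient is safe
    g = g.astype(t.data.dtype, copy=False)
    t.grad = g if t.grad is None else t.grad + g


# -- arithmetic --------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _coerce(a, b)
    req = _needs_grad(a, b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward, req)


def sub(a, b) -> Tensor:
    a, b = _coerce(a, b)
    req = _needs_grad(a, b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(a.data - b.data, (a, b), backward, req)


def mul(a, b) -> Tensor:
    a, b = _coerce(a, b)
    req = _needs_grad(a, b)

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward, req)


def neg(a) -> Tensor:
    a = _wrap(a)

    def backward(g):
        _accum(a, -g)

    return _make(-a.data, (a,), backward, a.requires_grad)


def power(a, k: float) -> Tensor:
    a = _wrap(a)
    k = float(k)

    def backward(g):
        _accum(a, g * k * np.power(a.data, k - 1.0))

    return _make(np.power(a.data, k), (a,), backward, a.requires_grad)


def matmul(a, b) -> Tensor:
    """2-D or batched matrix product; leading batch dims must match exactly."""
    a, b = _wrap(a), _wrap(b)
    req = _needs_grad(a, b)

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            _accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(a.data @ b.data, (a, b), backward, req)


# -- nonlinearities ----------------------------------------------------------

def relu(a) -> Tensor:
    a = _wrap(a)
    out_data = np.maximum(a.data, 0)

    def backward(g):
        _accum(a, g * (a.data > 0))

    return _make(out_data, (a,), backward, a.requires_grad)


def tanh(a) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), backward, a.requires_grad)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), backward, a.requires_grad)


def log(a) -> Tensor:
    a = _wrap(a)

    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward, a.requires_grad)


# -- reductions / shape ------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward,
                 a.requires_grad)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        count = a.data.size
    else:
        count = a.data.shape[axis]

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g / count, a.data.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g / count, a.data.shape))

    return _make(a.data.mean(axis=axis, keepdims=keepdims), (a,), backward,
                 a.requires_grad)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward, a.requires_grad)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward, a.requires_grad)


def concatenate(tensors, axis=-1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    req = _needs_grad(*tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, backward, req)


def broadcast_to(a, shape) -> Tensor:
    a = _wrap(a)

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))

    return _make(np.broadcast_to(a.data, shape).copy(), (a,), backward,
                 a.requires_grad)


def take_row(a, index: int) -> Tensor:
    """Select one slice along axis 0 (used to pull one particle out of a batch)."""
    a = _wrap(a)

    def backward(g):
        full = np.zeros_like(a.data)
        full[index] = g
        _accum(a, full)

    return _make(a.data[index], (a,), backward, a.requires_grad)


def softmax(a, axis=-1) -> Tensor:
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        # dL/dx = s * (g - sum(g*s))
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _accum(a, out_data * (g - dot))

    return _make(out_data, (a,), backward, a.requires_grad)


def segment_mean(a, lengths) -> Tensor:
    """Mean over consecutive row segments: (sum(lengths), C) -> (n_segments, C).

    The symmetric pooling step of the encoder for variable-size particles.
    """
    a = _wrap(a)
    lengths = np.asarray(lengths, dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    sums = np.add.reduceat(a.data, starts, axis=0)
    out_data = sums / lengths[:, None].astype(a.data.dtype)

    def backward(g):
        _accum(a, np.repeat(g / lengths[:, None].astype(g.dtype), lengths, axis=0))

    return _make(out_data, (a,), backward, a.requires_grad)


def chamfer_to_fixed(x_fixed: np.ndarray, xhat: Tensor) -> Tensor:
    """Symmetric Chamfer distance between a fixed point set and a generated one.

    Normalized by ``|x_fixed|`` on both terms. The fixed side carries no
    gradient (it is the input data); the generated side receives the exact
    gradient of the matched squared distances, with nearest-neighbour
    assignments treated as locally constant (they are, almost everywhere).
    """
    x = np.asarray(x_fixed)
    n = x.shape[0]
    xh = xhat.data
    # squared pairwise distances via the expansion trick
    d2 = (
        (x * x).sum(axis=1)[:, None]
        + (xh * xh).sum(axis=1)[None, :]
        - 2.0 * (x @ xh.T)
    )
    j_star = d2.argmin(axis=1)          # nearest generated point per input point
    m_star = d2.argmin(axis=0)          # nearest input point per generated point
    term1 = np.maximum(d2[np.arange(x.shape[0]), j_star], 0.0).sum()
    term2 = np.maximum(d2[m_star, np.arange(xh.shape[0])], 0.0).sum()
    value = (term1 + term2) / n

    def backward(g):
        grad = np.zeros_like(xh)
        # term 1: each input point pulls its matched generated point
        np.add.at(grad, j_star, (2.0 / n) * (xh[j_star] - x))
        # term 2: each generated point is pulled toward its nearest input point
        grad += (2.0 / n) * (xh - x[m_star])
        _accum(xhat, g * grad)

    return _make(np.asarray(value, dtype=xh.dtype), (xhat,), backward,
                 xhat.requires_grad)
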