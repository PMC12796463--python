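"""Neural-network building blocks on top of the autodiff tape.

Shapes follow the "rows are samples" convention: :class:`Linear` and
:class:`BatchNorm1d` act on ``(M, C)`` arrays; attention acts on
``(batch, n_points, channels)``.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor


class Module:
    """Base class with parameter/buffer discovery and train/eval switching."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self):
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map on the last axis; inputs are flattened to 2-D internally."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            return ag.add(ag.matmul(x, self.weight), self.bias)
        lead = x.shape[:-1]
        flat = ag.reshape(x, (-1, self.in_features))
        out = ag.add(ag.matmul(flat, self.weight), self.bias)
        return ag.reshape(out, lead + (self.out_features,))


class BatchNorm1d(Module):
    """Per-channel normalization over the sample axis with running statistics.

    Uses the biased variance both for normalization and for the running
    average; evaluation mode normalizes with the stored running statistics.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        lead = None
        if x.ndim != 2:
            lead = x.shape[:-1]
            x = ag.reshape(x, (-1, self.num_features))
        if self.training:
            mean = ag.tmean(x, axis=0, keepdims=True)
            centered = ag.sub(x, mean)
            var = ag.tmean(ag.mul(centered, centered), axis=0, keepdims=True)
            inv_std = ag.power(ag.add(var, self.eps), -0.5)
            xhat = ag.mul(centered, inv_std)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean.data.ravel()).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.ravel()).astype(np.float32)
        else:
            scale = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = ag.mul(ag.sub(x, self.running_mean.astype(x.data.dtype)),
                          scale.astype(x.data.dtype))
        out = ag.add(ag.mul(xhat, self.gamma), self.beta)
        if lead is not None:
            out = ag.reshape(out, lead + (self.num_features,))
        return out


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention over the point axis.

    Input and output are ``(batch, n_points, channels)``; channels must be
    divisible by the number of heads.
    """

    def __init__(self, channels: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if channels % n_heads:
            raise ValueError(
                f"channels ({channels}) not divisible by n_heads ({n_heads})")
        self.channels = channels
        self.n_heads = n_heads
        self.head_dim = channels // n_heads
        self.q_proj = Linear(channels, channels, rng)
        self.k_proj = Linear(channels, channels, rng)
        self.v_proj = Linear(channels, channels, rng)
        self.out_proj = Linear(channels, channels, rng)

    def _split_heads(self, x: Tensor, b: int, n: int) -> Tensor:
        x = ag.reshape(x, (b, n, self.n_heads, self.head_dim))
        return ag.transpose(x, (0, 2, 1, 3))  # (B, H, N, dk)

    def forward(self, x: Tensor) -> Tensor:
        b, n, _ = x.shape
        q = self._split_heads(self.q_proj(x), b, n)
        k = self._split_heads(self.k_proj(x), b, n)
        v = self._split_heads(self.v_proj(x), b, n)
        scores = ag.mul(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))),
                        1.0 / math.sqrt(self.head_dim))
        attn = ag.softmax(scores, axis=-1)
        ctx = ag.matmul(attn, v)                       # (B, H, N, dk)
        ctx = ag.transpose(ctx, (0, 2, 1, 3))          # (B, N, H, dk)
        ctx = ag.reshape(ctx, (b, n, self.channels))
        return self.out_proj(ctx)
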