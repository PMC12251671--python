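"""Transformer building blocks and the AdamW optimizer on the autodiff core.

Pre-norm blocks throughout: ``x + Attn(LN(x), LN(y))`` then
``x + FFN(LN(x))``. Cross-attention is the same block with a different
key/value stream. Everything runs in float32 by default; dtype follows
the parameters.
"""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor, gelu, layernorm, relu, softmax

__all__ = [
    "Linear", "LayerNorm", "MultiHeadAttention", "FeedForward",
    "TransformerBlock", "AdamW", "dropout",
]


class Module:
    """Base with recursive parameter collection."""

    def parameters(self) -> list:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        s = 1.0 / np.sqrt(d_in)
        self.W = Tensor(rng.uniform(-s, s, (d_in, d_out)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        flat = x.reshape(-1, x.shape[-1]) if x.ndim > 2 else x
        out = flat @ self.W + self.b
        return out.reshape(*lead, self.W.shape[1]) if x.ndim > 2 else out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        self.g = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.b = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layernorm(x, self.g, self.b, self.eps)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            train: bool) -> Tensor:
    if not train or rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate).astype(x.data.dtype)
    return x * Tensor(keep / (1.0 - rate))


class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng, drop: float = 0.0):
        if dim % heads:
            raise ValueError("hidden dim must be divisible by heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.drop = drop

    def _split(self, t: Tensor, B: int, T: int) -> Tensor:
        return t.reshape(B, T, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, kv: Tensor, train: bool = False,
                 rng=None) -> Tensor:
        B, Tq, d = x.shape
        Tk = kv.shape[1]
        if self.heads == 1:      # fast path: 3D batched matmuls
            q, k, v = self.wq(x), self.wk(kv), self.wv(kv)
            scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))
            attn = dropout(softmax(scores, axis=-1), self.drop, rng, train)
            return self.wo(attn @ v)
        q = self._split(self.wq(x), B, Tq)
        k = self._split(self.wk(kv), B, Tk)
        v = self._split(self.wv(kv), B, Tk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)
        attn = dropout(attn, self.drop, rng, train)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Tq, d)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, dim: int, mult: int, rng, drop: float = 0.0,
                 activation: str = "gelu"):
        self.fc1 = Linear(dim, dim * mult, rng)
        self.fc2 = Linear(dim * mult, dim, rng)
        self.drop = drop
        self.act = gelu if activation == "gelu" else relu

    def __call__(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        return self.fc2(dropout(self.act(self.fc1(x)), self.drop, rng,
                                train))


class TransformerBlock(Module):
    """Pre-norm attention + feed-forward block (self- or cross-attention)."""

    def __init__(self, dim: int, heads: int, rng, drop: float = 0.0,
                 ffn_mult: int = 4, activation: str = "gelu"):
        self.ln1 = LayerNorm(dim)
        self.ln_kv = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng, drop)
        self.ln2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_mult, rng, drop, activation)
        self.drop = drop

    def __call__(self, x: Tensor, kv: Tensor | None = None,
                 train: bool = False, rng=None) -> Tensor:
        xn = self.ln1(x)
        kvn = xn if kv is None else self.ln_kv(kv)
        x = x + dropout(self.attn(xn, kvn, train, rng), self.drop, rng, train)
        return x + self.ffn(self.ln2(x), train, rng)


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.wd:
                update = update + self.wd * p.data
            p.data = p.data - self.lr * update
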