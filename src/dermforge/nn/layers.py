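"""Parameterized layers built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d, conv_transpose2d, embedding

__all__ = [
    "Module", "Dense", "Conv2d", "ConvTranspose2d", "Embedding",
    "LayerNorm", "Dropout", "MultiHeadSelfAttention",
]


class Module:
    """Base class: recursively collects ``Tensor`` parameters.

    Parameters are discovered by attribute scan, in attribute insertion
    order, which makes ``state_dict`` ordering deterministic.
    """

    def parameters(self):
        out = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def param_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.shape}")
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 w_std: float | None = None):
        shape = (in_dim, out_dim)
        if w_std is None:
            self.w = Tensor(_glorot(rng, shape, in_dim, out_dim), requires_grad=True)
        else:
            self.w = Tensor(rng.normal(0.0, w_std, size=shape), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, w_std: float | None = None):
        shape = (out_ch, in_ch, k, k)
        fan_in = in_ch * k * k
        if w_std is None:
            self.w = Tensor(_glorot(rng, shape, fan_in, out_ch * k * k),
                            requires_grad=True)
        else:
            self.w = Tensor(rng.normal(0.0, w_std, size=shape), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, w_std: float | None = None):
        shape = (in_ch, out_ch, k, k)
        fan_in = in_ch * k * k
        if w_std is None:
            self.w = Tensor(_glorot(rng, shape, fan_in, out_ch * k * k),
                            requires_grad=True)
        else:
            self.w = Tensor(rng.normal(0.0, w_std, size=shape), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator,
                 w_std: float = 0.05):
        self.w = Tensor(rng.normal(0.0, w_std, size=(n, dim)), requires_grad=True)
        self.dim = dim

    def __call__(self, idx) -> Tensor:
        return embedding(idx, self.w)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = centered.pow(2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only when an rng is supplied (training)."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if rng is None or self.rate == 0.0:
            return x
        keep = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (B, T, E) sequences."""

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.q = Dense(embed_dim, embed_dim, rng)
        self.k = Dense(embed_dim, embed_dim, rng)
        self.v = Dense(embed_dim, embed_dim, rng)
        self.out = Dense(embed_dim, embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, e = x.shape
        h, d = self.n_heads, self.head_dim

        def split(z: Tensor) -> Tensor:
            return z.reshape(b, t, h, d).transpose(0, 2, 1, 3)  # (B, h, T, d)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, e)
        return self.out(ctx)
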