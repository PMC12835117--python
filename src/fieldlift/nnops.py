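"""Minimal neural-network operations on numpy arrays with autograd support.

All image tensors are channels-last ``(B, H, W, C)`` — on a single CPU the
im2col gather is several times cheaper in this layout than channels-first.
Convolution is lowered to one im2col gather plus one sgemm; `im2col`,
`matmul`, `relu` and `upsample2x` are registered as autograd primitives
with hand-written adjoints so every backward step is also a plain sgemm or
a 3x3 scatter-add, avoiding the generic (slow) tensordot adjoints.

Everything here is float32 and deterministic.
"""

from __future__ import annotations

import numpy as np
import autograd.numpy as anp
from autograd.extend import defvjp, primitive
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "conv2d", "matmul", "relu", "leaky_relu", "sigmoid", "upsample2x",
    "group_norm", "dense", "time_embedding", "conv_init", "dense_init",
]


def _out_hw(H: int, W: int, kh: int, kw: int, stride: int, pad: int):
    return (H + 2 * pad - kh) // stride + 1, (W + 2 * pad - kw) // stride + 1


@primitive
def im2col(x, kh, kw, stride, pad):
    """Gather 2D conv windows: (B,H,W,C) -> (B*Ho*Wo, kh*kw*C)."""
    B, H, W, C = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    Ho, Wo = _out_hw(H, W, kh, kw, stride, pad)
    s = x.strides
    win = as_strided(x, (B, Ho, Wo, kh, kw, C),
                     (s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]))
    return np.ascontiguousarray(win).reshape(B * Ho * Wo, kh * kw * C)


def _im2col_vjp(ans, x, kh, kw, stride, pad):
    B, H, W, C = x.shape
    Ho, Wo = _out_hw(H, W, kh, kw, stride, pad)

    def vjp(g):
        gc = g.reshape(B, Ho, Wo, kh, kw, C)
        Hp, Wp = H + 2 * pad, W + 2 * pad
        gx = np.zeros((B, Hp, Wp, C), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                gx[:, i:i + stride * Ho:stride, j:j + stride * Wo:stride, :] += gc[:, :, :, i, j, :]
        return gx[:, pad:Hp - pad, pad:Wp - pad, :] if pad else gx
    return vjp


defvjp(im2col, _im2col_vjp)


@primitive
def matmul(a, b):
    return a @ b


defvjp(matmul,
       lambda ans, a, b: lambda g: g @ b.T,
       lambda ans, a, b: lambda g: a.T @ g)


@primitive
def relu(x):
    return np.maximum(x, 0.0)


defvjp(relu, lambda ans, x: lambda g: g * (ans > 0))


def leaky_relu(x, slope: float = 0.2):
    return anp.maximum(x, slope * x)


@primitive
def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


defvjp(sigmoid, lambda ans, x: lambda g: g * ans * (1.0 - ans))


@primitive
def upsample2x(x):
    """Nearest-neighbour 2x upsampling of (B,H,W,C)."""
    return x.repeat(2, axis=1).repeat(2, axis=2)


defvjp(upsample2x, lambda ans, x: lambda g:
       g.reshape(g.shape[0], g.shape[1] // 2, 2, g.shape[2] // 2, 2, g.shape[3]).sum(axis=(2, 4)))


def conv2d(x, w, b, stride: int = 1, pad: int = 1):
    """2D convolution (cross-correlation), channels-last.

    x: (B,H,W,Cin); w: (kh,kw,Cin,Cout); b: (Cout,).
    """
    kh, kw, cin, cout = w.shape
    B, H, W, C = x.shape
    if C != cin:
        raise ValueError(f"input has {C} channels, kernel expects {cin}")
    Ho, Wo = _out_hw(H, W, kh, kw, stride, pad)
    cols = im2col(x, kh, kw, stride, pad)
    out = matmul(cols, anp.reshape(w, (kh * kw * cin, cout))) + b
    return anp.reshape(out, (B, Ho, Wo, cout))


def dense(x, w, b):
    """Affine layer: (B,Din) @ (Din,Dout) + (Dout,)."""
    return matmul(x, w) + b


def group_norm(x, groups: int, eps: float = 1e-5):
    """Per-sample group normalization of (B,H,W,C); no affine terms."""
    B, H, W, C = x.shape
    if C % groups:
        raise ValueError(f"channels {C} not divisible by groups {groups}")
    xg = anp.reshape(x, (B, H, W, groups, C // groups))
    mu = anp.mean(xg, axis=(1, 2, 4), keepdims=True)
    var = anp.mean(xg**2, axis=(1, 2, 4), keepdims=True) - mu**2
    xg = (xg - mu) / anp.sqrt(var + eps)
    return anp.reshape(xg, (B, H, W, C))


def time_embedding(t: int, dim: int) -> np.ndarray:
    """Sinusoidal embedding of an integer timestep (float32, shape (dim,))."""
    if dim % 2:
        raise ValueError("time embedding dim must be even")
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = float(t) * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)]).astype(np.float32)


def conv_init(rng: np.random.Generator, kh, kw, cin, cout, scale: float = 1.0):
    """He-style initialization for a conv kernel plus zero bias."""
    std = scale * np.sqrt(2.0 / (kh * kw * cin))
    w = (rng.standard_normal((kh, kw, cin, cout)) * std).astype(np.float32)
    return w, np.zeros(cout, dtype=np.float32)


def dense_init(rng: np.random.Generator, din, dout, scale: float = 1.0):
    std = scale * np.sqrt(2.0 / din)
    w = (rng.standard_normal((din, dout)) * std).astype(np.float32)
    return w, np.zeros(dout, dtype=np.float32)
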