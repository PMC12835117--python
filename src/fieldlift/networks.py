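"""Generator and discriminator of the adversarial diffusion translator.

The generator ``G(x_t, y, z, t)`` predicts the clean high-field slice
``x0`` from the current noisy chain state ``x_t`` (one slice), a 2.5D
stack of ``k`` adjacent conditioning (low-field) slices ``y``, a latent
code ``z`` and the timestep ``t``.  It is composed of

* a dual-branch feature extractor: separate residual blocks
  (conv -> group norm -> ReLU -> conv) for the noisy target and for the
  conditioning stack, so contrast-specific features are learned per
  branch before the channel-wise concatenation;
* a U-Net-style encoder-decoder with skip connections, whose stages are
  modulated by the latent code through adaptive group normalization
  (per-stage scale/shift from a 3-layer MLP on the 256-d ``z``) and by a
  sinusoidal embedding of ``t`` added as a per-stage channel bias.

The discriminator is a time-conditioned convolutional classifier scoring
whether a candidate ``x_{t-1}`` is a plausible denoised version of
``x_t``; it sees the channel concatenation of the two slices plus the
same sinusoidal time embedding.

Networks operate on [-1, 1]-normalized intensities; training and
inference wrappers handle the mapping from the package's [0, 1] volumes.
Everything is float32 numpy, differentiable through autograd, and
bit-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from .nnops import (conv2d, conv_init, dense, dense_init, group_norm,
                    leaky_relu, relu, sigmoid, time_embedding, upsample2x)

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "LatentCode", "Generator",
    "Discriminator", "build_generator", "build_discriminator",
    "generator_predict_x0", "discriminator_score", "flatten_params",
    "unflatten_params",
]

_Z_HIDDEN = 128


@dataclass
class LatentCode:
    """A standard-normal latent vector that modulates the generator stages."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float32)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("latent code must be finite")

    @classmethod
    def draw(cls, rng: np.random.Generator, z_dim: int = 256) -> "LatentCode":
        return cls(rng.standard_normal(z_dim))


@dataclass
class GeneratorConfig:
    k_adjacent: int = 3
    base_channels: int = 32
    depth: int = 3
    z_dim: int = 256
    mlp_layers: int = 3
    groupnorm_groups: int = 8
    time_embedding_dim: int = 64
    T: int = 4

    def __post_init__(self) -> None:
        if self.k_adjacent < 1 or self.k_adjacent % 2 == 0:
            raise ValueError("k_adjacent must be odd and >= 1")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.z_dim <= 0:
            raise ValueError("z_dim must be positive")
        if self.base_channels % self.groupnorm_groups:
            raise ValueError("base_channels must be divisible by groupnorm_groups")

    @property
    def channels(self) -> tuple:
        return tuple(self.base_channels * 2**l for l in range(self.depth))


@dataclass
class DiscriminatorConfig:
    base_channels: int = 32
    depth: int = 3
    time_embedding_dim: int = 64
    groupnorm_groups: int = 8
    T: int = 4

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


def _resblock_init(rng, p, name, cin, cout):
    p[f"{name}_in_w"], p[f"{name}_in_b"] = conv_init(rng, 3, 3, cin, cout)
    p[f"{name}_c1_w"], p[f"{name}_c1_b"] = conv_init(rng, 3, 3, cout, cout)
    p[f"{name}_c2_w"], p[f"{name}_c2_b"] = conv_init(rng, 3, 3, cout, cout, scale=0.5)


def _resblock(p, name, x, groups):
    h = conv2d(x, p[f"{name}_in_w"], p[f"{name}_in_b"])
    r = conv2d(h, p[f"{name}_c1_w"], p[f"{name}_c1_b"])
    r = relu(group_norm(r, groups))
    r = conv2d(r, p[f"{name}_c2_w"], p[f"{name}_c2_b"])
    return h + r


class Generator:
    """x0-predicting 2.5D generator; callable as ``G(x_t, y, z, t)``."""

    def __init__(self, config: GeneratorConfig | None = None,
                 rng: np.random.Generator | int | None = None, params: dict | None = None):
        self.config = config or GeneratorConfig()
        self.params = params if params is not None else self.init_params(np.random.default_rng(rng))

    def init_params(self, rng: np.random.Generator) -> dict:
        cfg = self.config
        C = cfg.base_channels
        chans = cfg.channels
        p: dict[str, np.ndarray] = {}
        _resblock_init(rng, p, "fe_x", 1, C)
        _resblock_init(rng, p, "fe_y", cfg.k_adjacent, C)
        p["in_w"], p["in_b"] = conv_init(rng, 3, 3, 2 * C, chans[0])

        def stage_init(name, ch):
            p[f"{name}_c1_w"], p[f"{name}_c1_b"] = conv_init(rng, 3, 3, ch, ch)
            p[f"{name}_zs_w"], p[f"{name}_zs_b"] = dense_init(rng, _Z_HIDDEN, 2 * ch, scale=0.1)
            p[f"{name}_tb_w"], p[f"{name}_tb_b"] = dense_init(rng, cfg.time_embedding_dim, ch, scale=0.1)

        for l in range(cfg.depth):
            stage_init(f"enc{l}", chans[l])
            if l < cfg.depth - 1:
                p[f"down{l}_w"], p[f"down{l}_b"] = conv_init(rng, 3, 3, chans[l], chans[l + 1])
        for l in range(cfg.depth - 2, -1, -1):
            p[f"dec{l}_in_w"], p[f"dec{l}_in_b"] = conv_init(rng, 3, 3, chans[l + 1] + chans[l], chans[l])
            stage_init(f"dec{l}", chans[l])
        p["out_w"], p["out_b"] = conv_init(rng, 3, 3, chans[0], 1, scale=0.5)

        dims = [cfg.z_dim] + [_Z_HIDDEN] * cfg.mlp_layers
        for i in range(cfg.mlp_layers):
            p[f"zmlp{i}_w"], p[f"zmlp{i}_b"] = dense_init(rng, dims[i], dims[i + 1])
        p["tmlp_w"], p["tmlp_b"] = dense_init(rng, cfg.time_embedding_dim, cfg.time_embedding_dim)
        return p

    # -- functional forward (traced by autograd during training) --

    def apply(self, params: dict, x_t, y, z, t: int):
        """Forward pass on batched arrays x_t (B,H,W), y (B,H,W,k), z (B,z_dim)."""
        cfg = self.config
        if not 1 <= int(t) <= cfg.T:
            raise ValueError(f"t must be in [1, {cfg.T}], got {t}")
        B, H, W = np.shape(x_t)[0], np.shape(x_t)[1], np.shape(x_t)[2]
        if np.shape(y)[:3] != (B, H, W) or np.shape(y)[3] != cfg.k_adjacent:
            raise ValueError(f"conditioning stack must be (B,H,W,{cfg.k_adjacent}), got {np.shape(y)}")
        if np.shape(z) != (B, cfg.z_dim):
            raise ValueError(f"z must be (B,{cfg.z_dim}), got {np.shape(z)}")
        g = cfg.groupnorm_groups

        hz = z
        for i in range(cfg.mlp_layers):
            hz = dense(hz, params[f"zmlp{i}_w"], params[f"zmlp{i}_b"])
            if i < cfg.mlp_layers - 1:
                hz = relu(hz)
        temb = time_embedding(t, cfg.time_embedding_dim)[None, :] * np.ones((B, 1), np.float32)
        ht = relu(dense(temb, params["tmlp_w"], params["tmlp_b"]))

        def stage(name, h, ch):
            # conv -> adaptive group norm (z scale/shift, t bias) -> relu
            ss = dense(hz, params[f"{name}_zs_w"], params[f"{name}_zs_b"])
            scale = anp.reshape(ss[:, :ch], (B, 1, 1, ch))
            shift = anp.reshape(ss[:, ch:], (B, 1, 1, ch))
            tb = anp.reshape(dense(ht, params[f"{name}_tb_w"], params[f"{name}_tb_b"]), (B, 1, 1, ch))
            r = conv2d(h, params[f"{name}_c1_w"], params[f"{name}_c1_b"])
            r = group_norm(r, g) * (1.0 + scale) + shift + tb
            return relu(r)

        hx = _resblock(params, "fe_x", anp.reshape(x_t, (B, H, W, 1)), g)
        hy = _resblock(params, "fe_y", y, g)
        h = anp.concatenate([hx, hy], axis=3)
        h = conv2d(h, params["in_w"], params["in_b"])

        chans = cfg.channels
        skips = []
        for l in range(cfg.depth):
            h = stage(f"enc{l}", h, chans[l])
            if l < cfg.depth - 1:
                skips.append(h)
                h = relu(conv2d(h, params[f"down{l}_w"], params[f"down{l}_b"], stride=2))
        for l in range(cfg.depth - 2, -1, -1):
            h = anp.concatenate([upsample2x(h), skips[l]], axis=3)
            h = relu(conv2d(h, params[f"dec{l}_in_w"], params[f"dec{l}_in_b"]))
            h = stage(f"dec{l}", h, chans[l])
        out = conv2d(h, params["out_w"], params["out_b"])
        return anp.reshape(out, (B, H, W))

    def __call__(self, x_t, y, z, t: int) -> np.ndarray:
        x_t = np.asarray(x_t, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if isinstance(z, LatentCode):
            z = z.z
        z = np.asarray(z, dtype=np.float32)
        single = x_t.ndim == 2
        if single:
            x_t, y, z = x_t[None], y[None], z[None]
        out = self.apply(self.params, x_t, y, z, t)
        return out[0] if single else out

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


class Discriminator:
    """Time-conditioned convolutional critic on (candidate, x_t) slice pairs."""

    def __init__(self, config: DiscriminatorConfig | None = None,
                 rng: np.random.Generator | int | None = None, params: dict | None = None):
        self.config = config or DiscriminatorConfig()
        self.params = params if params is not None else self.init_params(np.random.default_rng(rng))

    def init_params(self, rng: np.random.Generator) -> dict:
        cfg = self.config
        C = cfg.base_channels
        p: dict[str, np.ndarray] = {}
        p["in_w"], p["in_b"] = conv_init(rng, 3, 3, 2, C)
        ch = C
        for l in range(cfg.depth):
            nxt = ch * 2
            p[f"d{l}_w"], p[f"d{l}_b"] = conv_init(rng, 3, 3, ch, nxt)
            p[f"d{l}_tb_w"], p[f"d{l}_tb_b"] = dense_init(rng, cfg.time_embedding_dim, nxt, scale=0.1)
            ch = nxt
        p["head_w"], p["head_b"] = dense_init(rng, ch, 1)
        return p

    def apply_logit(self, params: dict, candidate, x_t, t: int):
        cfg = self.config
        if not 1 <= int(t) <= cfg.T:
            raise ValueError(f"t must be in [1, {cfg.T}], got {t}")
        if np.shape(candidate) != np.shape(x_t):
            raise ValueError(f"candidate shape {np.shape(candidate)} != x_t shape {np.shape(x_t)}")
        B = np.shape(candidate)[0]
        temb = time_embedding(t, cfg.time_embedding_dim)[None, :] * np.ones((B, 1), np.float32)
        h = anp.concatenate([anp.reshape(candidate, np.shape(candidate) + (1,)),
                             anp.reshape(x_t, np.shape(x_t) + (1,))], axis=3)
        h = leaky_relu(conv2d(h, params["in_w"], params["in_b"]))
        ch = cfg.base_channels
        for l in range(cfg.depth):
            nxt = ch * 2
            h = conv2d(h, params[f"d{l}_w"], params[f"d{l}_b"], stride=2)
            tb = anp.reshape(dense(temb, params[f"d{l}_tb_w"], params[f"d{l}_tb_b"]), (B, 1, 1, nxt))
            h = leaky_relu(group_norm(h, self.config.groupnorm_groups) + tb)
            ch = nxt
        pooled = anp.mean(h, axis=(1, 2))
        return anp.reshape(dense(pooled, params["head_w"], params["head_b"]), (B,))

    def apply_score(self, params: dict, candidate, x_t, t: int):
        return sigmoid(self.apply_logit(params, candidate, x_t, t))

    def logit(self, candidate, x_t, t: int) -> np.ndarray:
        candidate = np.asarray(candidate, dtype=np.float32)
        x_t = np.asarray(x_t, dtype=np.float32)
        single = candidate.ndim == 2
        if single:
            candidate, x_t = candidate[None], x_t[None]
        out = self.apply_logit(self.params, candidate, x_t, t)
        return out[0] if single else out

    def score(self, candidate, x_t, t: int):
        """Probability in (0, 1) that the candidate is a real denoised slice."""
        lg = self.logit(candidate, x_t, t)
        s = np.clip(sigmoid(np.atleast_1d(np.asarray(lg, dtype=np.float64))), 1e-12, 1.0 - 1e-12)
        return float(s[0]) if np.ndim(lg) == 0 else s

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


# -- module-level conveniences mirroring the functional surface --

def build_generator(cfg: GeneratorConfig | None = None, rng=None) -> Generator:
    return Generator(cfg, rng=rng)


def build_discriminator(cfg: DiscriminatorConfig | None = None, rng=None) -> Discriminator:
    return Discriminator(cfg, rng=rng)


def generator_predict_x0(G: Generator, x_t, y, z, t: int) -> np.ndarray:
    return G(x_t, y, z, t)


def discriminator_score(D: Discriminator, candidate, x_t, t: int):
    return D.score(candidate, x_t, t)


def flatten_params(params: dict, prefix: str = "") -> dict:
    return {prefix + k: v for k, v in params.items()}


def unflatten_params(flat: dict, prefix: str) -> dict:
    n = len(prefix)
    return {k[n:]: v for k, v in flat.items() if k.startswith(prefix)}
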