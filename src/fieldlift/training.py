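"""Adversarial training of the few-step diffusion translator.

Each step draws a timestep t uniformly from {1..T}, builds a jointly
correct (x_{t-1}, x_t) draw from the forward chain on the clean target
slice, lets the generator predict x0 from (x_t, conditioning stack, z, t),
pushes the prediction through the exact posterior to get a fake x_{t-1},
and then updates the discriminator on the two-term GAN objective (real
pairs contribute log D, fakes log(1-D)) followed by the generator on the
non-saturating adversarial loss plus an L1 data term weighted by lambda1.

Both updates run through autograd on the functional network forwards, so
discriminator gradients can never leak into generator parameters and vice
versa.  Losses are computed from logits in softplus form for numerical
stability; the reported values equal the textbook -log D expressions.

Intensities: slices enter the diffusion chain on the [-1, 1] scale
(volumes are stored on [0, 1]); the L1 loss lives on that scale too.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import make_vjp, value_and_grad

from . import diffusion
from .diffusion import NoiseSchedule, build_schedule, posterior_sample
from .io import VolumePair, read_manifest, load_pair
from .networks import (Discriminator, DiscriminatorConfig, Generator,
                       GeneratorConfig)

__all__ = [
    "TrainConfig", "SliceStack", "LossRecord", "Adam",
    "make_2p5d_stacks", "sample_training_pair", "draw_timestep",
    "discriminator_loss", "generator_loss", "train_step", "fit",
    "save_checkpoint", "load_checkpoint",
]

F32 = np.float32


@dataclass
class TrainConfig:
    """Hyperparameters of the adversarial diffusion training run."""

    lr_generator: float = 1.5e-4
    lr_discriminator: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    lambda1: float = 0.5
    T: int = 4
    beta_min: float = 0.1
    beta_max: float = 20.0
    batch_size: int = 4
    epochs: int = 1
    max_steps: int | None = None
    k_adjacent: int = 3
    base_channels: int = 32
    depth: int = 3
    z_dim: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_generator, self.lr_discriminator) <= 0:
            raise ValueError("learning rates must be positive")
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(k_adjacent=self.k_adjacent, base_channels=self.base_channels,
                               depth=self.depth, z_dim=self.z_dim, T=self.T)

    def discriminator_config(self) -> DiscriminatorConfig:
        return DiscriminatorConfig(base_channels=max(8, self.base_channels // 2),
                                   depth=self.depth, T=self.T,
                                   groupnorm_groups=min(8, max(8, self.base_channels // 2)))

    def schedule(self) -> NoiseSchedule:
        return build_schedule(self.T, self.beta_min, self.beta_max)


@dataclass
class SliceStack:
    """One 2.5D training/inference sample.

    ``y_stack`` holds k adjacent conditioning slices (H, W, k);
    ``x0_center`` is the aligned clean target center slice (H, W).
    """

    y_stack: np.ndarray
    x0_center: np.ndarray
    subject_id: str = ""
    contrast: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.y_stack.ndim != 3 or self.y_stack.shape[2] % 2 == 0:
            raise ValueError("y_stack must be (H, W, k) with odd k")
        if self.x0_center.shape != self.y_stack.shape[:2]:
            raise ValueError("x0_center must match the stack's slice shape")


@dataclass
class LossRecord:
    step: int
    d_loss: float
    g_adv_loss: float
    g_l1_loss: float
    t_drawn: int

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.d_loss, self.g_adv_loss, self.g_l1_loss))):
            raise FloatingPointError(f"non-finite loss at step {self.step}: {self}")


def make_2p5d_stacks(pair: VolumePair, k_adjacent: int) -> list[SliceStack]:
    """One stack per axial slice (last axis), edge-replicated at the borders."""
    if k_adjacent % 2 == 0 or k_adjacent < 1:
        raise ValueError(f"k_adjacent must be odd, got {k_adjacent}")
    depth = pair.conditioning.shape[2]
    half = k_adjacent // 2
    stacks = []
    for idx in range(depth):
        neighbors = np.clip(np.arange(idx - half, idx + half + 1), 0, depth - 1)
        stacks.append(SliceStack(
            y_stack=np.ascontiguousarray(pair.conditioning[:, :, neighbors], dtype=F32),
            x0_center=np.ascontiguousarray(pair.target[:, :, idx], dtype=F32),
            subject_id=pair.subject_id, contrast=pair.contrast, slice_index=idx,
        ))
    return stacks


def draw_timestep(rng: np.random.Generator, T: int) -> int:
    """Uniform draw from {1..T}."""
    return int(rng.integers(1, T + 1))


def sample_training_pair(x0, t: int, sched: NoiseSchedule, rng: np.random.Generator | None = None,
                         noises=None):
    """A coherent (x_{t-1}, x_t) draw from the forward chain.

    x_{t-1} is drawn from the exact marginal at t-1, then x_t from the
    one-step kernel, so the pair has the correct joint law.  At t=1 the
    marginal is degenerate and x_{t-1} = x0 exactly.
    """
    if not 1 <= t <= sched.T:
        raise ValueError(f"t must be in [1, {sched.T}], got {t}")
    if noises is None:
        if rng is None:
            raise ValueError("provide either rng or explicit noises")
        noises = (rng.standard_normal(np.shape(x0)).astype(x0.dtype),
                  rng.standard_normal(np.shape(x0)).astype(x0.dtype))
    x_prev = diffusion.forward_marginal(x0, t - 1, sched, noises[0])
    x_t = diffusion.forward_step(x_prev, t, sched, noises[1])
    return x_prev, x_t


def _clip_prob(p):
    return np.clip(np.asarray(p, dtype=np.float64), 1e-12, 1.0 - 1e-12)


def discriminator_loss(D, x_prev_real, x_prev_fake, x_t, t: int) -> float:
    """Two-term GAN objective (as minimized): mean of -log D(real) - log(1 - D(fake)).

    ``D`` only needs a ``score(candidate, x_t, t)`` method, so probe
    discriminators with fixed outputs work as well as trained ones.
    """
    d_r = _clip_prob(D.score(x_prev_real, x_t, t))
    d_f = _clip_prob(D.score(x_prev_fake, x_t, t))
    return float(np.mean(-np.log(d_r)) + np.mean(-np.log(1.0 - d_f)))


def generator_loss(D, x_prev_fake, x_t, t: int, x0_hat, x0_true, lambda1: float) -> float:
    """Non-saturating adversarial loss plus lambda1-weighted L1 data term."""
    if lambda1 < 0:
        raise ValueError("lambda1 must be >= 0")
    d_f = _clip_prob(D.score(x_prev_fake, x_t, t))
    adv = float(np.mean(-np.log(d_f)))
    l1 = float(np.mean(np.abs(np.asarray(x0_hat, np.float64) - np.asarray(x0_true, np.float64))))
    return adv + lambda1 * l1


class Adam:
    """Adam over a flat dict of float32 arrays."""

    def __init__(self, lr: float, beta1: float = 0.5, beta2: float = 0.9, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict | None = None
        self.v: dict | None = None
        self.t = 0

    def update(self, params: dict, grads: dict) -> dict:
        if self.m is None:
            self.m = {k: np.zeros_like(v) for k, v in params.items()}
            self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        new = {}
        for k, p in params.items():
            g = np.asarray(grads[k], dtype=p.dtype)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            new[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return new

    def state_arrays(self, prefix: str) -> dict:
        out = {}
        if self.m is not None:
            out.update({f"{prefix}m/{k}": v for k, v in self.m.items()})
            out.update({f"{prefix}v/{k}": v for k, v in self.v.items()})
        return out

    def load_state(self, arrays: dict, prefix: str, t: int) -> None:
        m = {k[len(prefix) + 2:]: v for k, v in arrays.items() if k.startswith(prefix + "m/")}
        v = {k[len(prefix) + 2:]: v for k, v in arrays.items() if k.startswith(prefix + "v/")}
        self.m = m or None
        self.v = v or None
        self.t = t


def _to_signed(x):
    """[0, 1] volume intensity -> [-1, 1] network scale."""
    return (2.0 * np.asarray(x, dtype=F32) - 1.0).astype(F32)


def _softplus(x):
    return anp.logaddexp(0.0, x)


def train_step(batch: list[SliceStack], G: Generator, D: Discriminator,
               opt_g: Adam, opt_d: Adam, sched: NoiseSchedule, cfg: TrainConfig,
               rng: np.random.Generator, step: int = 0) -> LossRecord:
    """One discriminator update followed by one generator update."""
    if not batch:
        raise ValueError("batch is empty")
    ys = _to_signed(np.stack([s.y_stack for s in batch]))
    x0 = _to_signed(np.stack([s.x0_center for s in batch]))
    B = x0.shape[0]

    t = draw_timestep(rng, sched.T)
    noises = (rng.standard_normal(x0.shape).astype(F32), rng.standard_normal(x0.shape).astype(F32))
    x_prev_real, x_t = sample_training_pair(x0, t, sched, noises=noises)
    z = rng.standard_normal((B, cfg.z_dim)).astype(F32)
    post_noise = rng.standard_normal(x0.shape).astype(F32)

    # Trace the generator forward once; its value feeds the discriminator
    # update and its stored tape is reused for the generator update.
    vjp_x0, x0_hat_val = make_vjp(lambda pg: G.apply(pg, x_t, ys, z, t))(G.params)
    x_fake_val = posterior_sample(x0_hat_val, x_t, t, sched, post_noise)

    # --- discriminator update (generator weights fixed; fake is a value) ---
    def d_objective(pd):
        logit_r = D.apply_logit(pd, x_prev_real, x_t, t)
        logit_f = D.apply_logit(pd, x_fake_val, x_t, t)
        return anp.mean(_softplus(-logit_r)) + anp.mean(_softplus(logit_f))

    d_val, d_grad = value_and_grad(d_objective)(D.params)
    D.params = opt_d.update(D.params, d_grad)

    # --- generator update against the freshly updated discriminator ---
    def g_head(x0_hat):
        x_fake = posterior_sample(x0_hat, x_t, t, sched, post_noise)
        logit_f = D.apply_logit(D.params, x_fake, x_t, t)
        return anp.mean(_softplus(-logit_f)) + cfg.lambda1 * anp.mean(anp.abs(x0_hat - x0))

    head_vjp, g_val = make_vjp(g_head)(x0_hat_val)
    g_grad = vjp_x0(head_vjp(1.0))

    g_l1 = float(np.mean(np.abs(x0_hat_val - x0)))
    g_adv = float(g_val) - cfg.lambda1 * g_l1

    G.params = opt_g.update(G.params, g_grad)
    return LossRecord(step=step, d_loss=float(d_val), g_adv_loss=g_adv, g_l1_loss=g_l1, t_drawn=t)


def _load_stacks(manifest: pd.DataFrame, contrast: str, k_adjacent: int) -> list[SliceStack]:
    rows = manifest[manifest["contrast"] == contrast]
    if rows.empty:
        raise ValueError(f"manifest has no rows for contrast {contrast!r}")
    stacks = []
    for _, row in rows.iterrows():
        stacks.extend(make_2p5d_stacks(load_pair(row), k_adjacent))
    return stacks


def train_on_stacks(stacks: list[SliceStack], cfg: TrainConfig, resume=None,
                    log_every: int = 0):
    """Core training loop over prepared 2.5D stacks.

    Returns ``(G, D, opt_g, opt_d, rng, step, history)``; used by both the
    manifest-level :func:`fit` and the estimator interface.
    """
    if not stacks:
        raise ValueError("no training stacks")
    sched = cfg.schedule()
    if resume is not None:
        G, D, opt_g, opt_d, rng, start_step, history, epoch0, pos0 = _restore(resume, cfg)
    else:
        rng = np.random.default_rng(cfg.seed)
        G = Generator(cfg.generator_config(), rng=rng)
        D = Discriminator(cfg.discriminator_config(), rng=rng)
        opt_g = Adam(cfg.lr_generator, cfg.adam_beta1, cfg.adam_beta2)
        opt_d = Adam(cfg.lr_discriminator, cfg.adam_beta1, cfg.adam_beta2)
        start_step, history, epoch0, pos0 = 0, [], 0, 0

    n = len(stacks)
    step = start_step
    epoch, pos = epoch0, pos0
    done = False
    while epoch < cfg.epochs and not done:
        # the shuffle is a pure function of (seed, epoch) so a resumed run
        # replays the identical batch order
        order = np.random.default_rng(np.random.SeedSequence([cfg.seed, epoch])).permutation(n)
        while pos < n:
            batch = [stacks[i] for i in order[pos:pos + cfg.batch_size]]
            rec = train_step(batch, G, D, opt_g, opt_d, sched, cfg, rng, step=step)
            history.append(asdict(rec))
            if log_every and step % log_every == 0:
                print(f"step={rec.step} t={rec.t_drawn} d={rec.d_loss:.4f} "
                      f"g_adv={rec.g_adv_loss:.4f} g_l1={rec.g_l1_loss:.4f}", flush=True)
            step += 1
            pos += cfg.batch_size
            if cfg.max_steps is not None and step - start_step >= cfg.max_steps:
                done = True
                break
        if pos >= n:
            epoch += 1
            pos = 0
    hist = pd.DataFrame(history, columns=["step", "d_loss", "g_adv_loss", "g_l1_loss", "t_drawn"])
    state = {"epoch": epoch, "pos": pos}
    return G, D, opt_g, opt_d, rng, step, hist, state


def fit(manifest, cfg: TrainConfig, contrast: str = "T1", out_dir=None,
        resume=None, log_every: int = 0):
    """Train a generator/discriminator pair for one contrast.

    ``manifest`` is a path to a dataset manifest CSV or the DataFrame
    itself.  Returns ``(generator, discriminator, history)`` where history
    is a DataFrame with one row per executed step.  When ``out_dir`` is
    given, a checkpoint and the loss history are written there; passing a
    checkpoint path as ``resume`` continues a run bit-identically (the
    checkpoint stores parameters, optimizer moments and the RNG state).
    """
    if isinstance(manifest, (str, Path)):
        manifest = read_manifest(manifest)
    if manifest.empty:
        raise ValueError("manifest is empty")
    stacks = _load_stacks(manifest, contrast, cfg.k_adjacent)
    G, D, opt_g, opt_d, rng, step, hist, loop_state = train_on_stacks(
        stacks, cfg, resume=resume, log_every=log_every)
    G.contrast = contrast
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / f"{contrast}_checkpoint.npz", G, D, cfg, contrast,
                        opt_g=opt_g, opt_d=opt_d, rng=rng, step=step, history=hist,
                        loop_state=loop_state)
        hist.to_csv(out_dir / f"{contrast}_loss_history.csv", index=False)
    return G, D, hist


def save_checkpoint(path, G: Generator, D: Discriminator | None, cfg: TrainConfig,
                    contrast: str, opt_g: Adam | None = None, opt_d: Adam | None = None,
                    rng: np.random.Generator | None = None, step: int = 0,
                    history: pd.DataFrame | None = None,
                    loop_state: dict | None = None) -> None:
    """Single-file archive: configs + weights + schedule + optimizer/RNG state."""
    meta = {
        "train_config": asdict(cfg),
        "contrast": contrast,
        "step": int(step),
        "opt_t": [opt_g.t if opt_g else 0, opt_d.t if opt_d else 0],
        "rng_state": rng.bit_generator.state if rng is not None else None,
        "history": history.to_dict("list") if history is not None else None,
        "loop_state": loop_state or {"epoch": 0, "pos": 0},
    }
    arrays = {f"g/{k}": v for k, v in G.params.items()}
    if D is not None:
        arrays.update({f"d/{k}": v for k, v in D.params.items()})
    if opt_g is not None:
        arrays.update(opt_g.state_arrays("og"))
    if opt_d is not None:
        arrays.update(opt_d.state_arrays("od"))
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Returns ``(generator, discriminator, train_config, meta)``."""
    with np.load(path) as archive:
        arrays = {k: archive[k] for k in archive.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    tc = meta["train_config"]
    tc["max_steps"] = tc.get("max_steps")
    cfg = TrainConfig(**tc)
    g_params = {k[2:]: arrays[k] for k in arrays if k.startswith("g/")}
    d_params = {k[2:]: arrays[k] for k in arrays if k.startswith("d/")}
    G = Generator(cfg.generator_config(), params=g_params)
    G.contrast = meta.get("contrast")
    D = Discriminator(cfg.discriminator_config(), params=d_params) if d_params else None
    meta["_arrays"] = arrays
    return G, D, cfg, meta


def _restore(path, cfg: TrainConfig):
    G, D, _, meta = load_checkpoint(path)
    arrays = meta.pop("_arrays")
    opt_g = Adam(cfg.lr_generator, cfg.adam_beta1, cfg.adam_beta2)
    opt_d = Adam(cfg.lr_discriminator, cfg.adam_beta1, cfg.adam_beta2)
    opt_g.load_state(arrays, "og", meta["opt_t"][0])
    opt_d.load_state(arrays, "od", meta["opt_t"][1])
    rng = np.random.default_rng()
    rng.bit_generator.state = meta["rng_state"]
    history = [dict(zip(meta["history"], vals)) for vals in zip(*meta["history"].values())] \
        if meta.get("history") else []
    loop = meta.get("loop_state") or {"epoch": 0, "pos": 0}
    return G, D, opt_g, opt_d, rng, meta["step"], history, loop["epoch"], loop["pos"]
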