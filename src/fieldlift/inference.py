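"""Whole-volume enhancement and side-by-side montage export.

A conditioning (low-field) volume is enhanced slice by slice along the
axial (last) axis: for each slice the 2.5D conditioning stack is built,
the T-step reverse diffusion chain is run with the trained generator, and
the predicted clean center slice is placed into the output volume.  Each
slice gets its own RNG derived from (global seed, slice index), so
enhancing any sub-range of slices reproduces exactly the corresponding
slices of a full-volume run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .diffusion import NoiseSchedule, reverse_sample
from .networks import Generator

__all__ = ["EnhancementResult", "enhance_volume", "export_montage"]

F32 = np.float32


@dataclass
class EnhancementResult:
    """Enhanced volume plus reproducibility metadata."""

    enhanced: np.ndarray
    slice_seeds: list
    n_generator_calls: int
    clip_fraction: float
    metadata: dict = field(default_factory=dict)


def _stack_for_slice(volume: np.ndarray, idx: int, k: int) -> np.ndarray:
    depth = volume.shape[2]
    half = k // 2
    neighbors = np.clip(np.arange(idx - half, idx + half + 1), 0, depth - 1)
    return np.ascontiguousarray(volume[:, :, neighbors], dtype=F32)


def enhance_volume(conditioning, G: Generator, sched: NoiseSchedule, seed: int = 0,
                   fixed_z: bool = False, slice_range=None, contrast: str | None = None,
                   checkpoint_id: str | None = None) -> EnhancementResult:
    """Enhance a [0, 1] conditioning volume with a trained generator.

    Runs exactly ``depth * T`` generator calls (T per slice).  ``fixed_z``
    keeps one latent code per slice instead of redrawing it every reverse
    step.  ``slice_range`` restricts enhancement to a sub-range of axial
    slices (others are left as the conditioning input).
    """
    trained_for = getattr(G, "contrast", None)
    if contrast is not None and trained_for is not None and contrast != trained_for:
        raise ValueError(f"generator was trained for {trained_for!r}, requested {contrast!r}")
    vol = np.asarray(conditioning, dtype=F32)
    if vol.ndim != 3:
        raise ValueError(f"conditioning must be a 3D volume, got shape {vol.shape}")
    cfg = G.config
    signed = (2.0 * vol - 1.0).astype(F32)
    out = vol.copy()
    indices = range(vol.shape[2]) if slice_range is None else slice_range

    calls = 0
    clipped = 0
    total = 0
    slice_seeds = []

    def predictor(x_t, y, z, t):
        nonlocal calls
        calls += 1
        return G.apply(G.params, x_t[None], y[None], z[None], t)[0]

    for idx in indices:
        ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(int(idx),))
        slice_seeds.append(int(ss.generate_state(1)[0]))
        rng = np.random.default_rng(ss)
        y = _stack_for_slice(signed, idx, cfg.k_adjacent)
        z_fixed = rng.standard_normal(cfg.z_dim).astype(F32)

        def z_source(t, r, _z=z_fixed):
            return _z if fixed_z else r.standard_normal(cfg.z_dim).astype(F32)

        x0 = reverse_sample(predictor, y, sched, rng, shape=y.shape[:2], z_source=z_source)
        x0 = (np.asarray(x0) + 1.0) / 2.0
        clipped += int(np.sum((x0 < 0) | (x0 > 1)))
        total += x0.size
        out[:, :, idx] = np.clip(x0, 0.0, 1.0)

    return EnhancementResult(
        enhanced=out,
        slice_seeds=slice_seeds,
        n_generator_calls=calls,
        clip_fraction=clipped / max(total, 1),
        metadata={"T": sched.T, "seed": int(seed), "fixed_z": fixed_z,
                  "checkpoint_id": checkpoint_id, "contrast": contrast or trained_for},
    )


def export_montage(volumes, out_dir, slice_range=None, gutter: int = 8,
                   prefix: str = "frame") -> list:
    """Write per-slice side-by-side PNG frames with a shared [0, 1] window.

    ``volumes`` is an ordered sequence of co-registered 3D arrays (e.g.
    target, conditioning, enhanced).  Frame width is
    ``n_panels * W + (n_panels - 1) * gutter`` pixels.
    """
    volumes = [np.asarray(v, dtype=np.float64) for v in volumes]
    if not volumes:
        raise ValueError("no volumes given")
    shape = volumes[0].shape
    for v in volumes[1:]:
        if v.shape != shape:
            raise ValueError(f"volumes must share a grid: {v.shape} vs {shape}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    indices = range(shape[2]) if slice_range is None else slice_range

    paths = []
    for idx in indices:
        panels = [np.clip(v[:, :, idx], 0.0, 1.0) for v in volumes]
        g = np.full((shape[0], gutter), 1.0)
        strip = panels[0]
        for p in panels[1:]:
            strip = np.concatenate([strip, g, p], axis=1)
        frame = (strip * 255).round().astype(np.uint8)
        path = out_dir / f"{prefix}_{idx:04d}.png"
        iio.imwrite(path, frame)
        paths.append(path)
    return paths
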