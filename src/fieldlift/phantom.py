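"""Synthetic paired high-field / ultra-low-field brain phantoms.

Every other module in the package is exercised against volumes from this
generator, so no external download is ever needed.  A phantom is a set of
nested, smoothly deformed ellipsoidal shells (scalp/skull, CSF, grey
matter, white matter) with optional ellipsoidal lesions carved into the
white matter.  Multi-contrast appearance comes from a per-label intensity
table; the low-field arm is produced by a four-stage degradation that
mimics the stated deficits of ultra-low-field acquisition — coarse
acquisition matrix, compressed tissue contrast, receive-field
inhomogeneity and low SNR — followed by trilinear resampling back onto
the common 1 mm-style grid, so both arms of a pair are co-registered by
construction.

The degradation is deliberately a minimal qualitative model: no Bloch
simulation, no k-space sampling, no motion or interference artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .io import MANIFEST_COLUMNS, write_volume

__all__ = [
    "LabelMap",
    "ContrastTable",
    "DegradeSpec",
    "make_label_map",
    "synthesize_contrasts",
    "degrade_to_ulf",
    "make_paired_dataset",
    "default_contrast_table",
    "default_degrade_specs",
]

# tissue labels
BACKGROUND, CSF, GM, WM, SKULL, LESION = 0, 1, 2, 3, 4, 5
BRAIN_LABELS = (CSF, GM, WM)

# normalized-radius thresholds of the nested shells (fractions of the head
# semi-axes): WM core, GM ribbon, CSF rim, skull/scalp rind
_SHELLS = ((WM, 0.50), (GM, 0.68), (CSF, 0.78), (SKULL, 0.92))

# acquisition-matrix ratios between the high-field and point-of-care arms
# (high-field matrix / PoC matrix per axis, through-plane heavily coarsened
# for T1/FLAIR, clamped at 1 where the PoC matrix is not coarser)
_POC_FACTORS = {
    "T1": (256 / 112, 256 / 112, 176 / 36),
    "T2": (512 / 146, 461 / 146, 1.0),
    "FLAIR": (232 / 138, 256 / 138, 176 / 36),
}


@dataclass
class LabelMap:
    """Integer tissue labels on a regular grid (0 = background)."""

    labels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def brain_mask(self) -> np.ndarray:
        return np.isin(self.labels, BRAIN_LABELS) | (self.labels >= LESION)

    @property
    def head_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class ContrastTable:
    """Per-label mean intensity and intra-class sd for each contrast.

    ``values[contrast][label] = (mean, sd)`` with means on [0, 1].
    """

    values: dict

    def __post_init__(self) -> None:
        for contrast, table in self.values.items():
            means = [m for m, _ in table.values()]
            if any(not 0.0 <= m <= 1.0 for m in means):
                raise ValueError(f"{contrast}: means must lie in [0, 1]")
            if any(s < 0 for _, s in table.values()):
                raise ValueError(f"{contrast}: sds must be >= 0")
            spread = max(means) - min(means)
            if len(means) >= 2 and spread <= 0.05:
                raise ValueError(f"{contrast}: needs two labels differing by > 0.05")

    @property
    def contrasts(self) -> tuple:
        return tuple(self.values)


def default_contrast_table() -> ContrastTable:
    """Default multi-contrast appearance (dimensionless [0, 1] intensities).

    Means follow the canonical ordering of brain tissue: T1 (WM bright,
    CSF dark), T2 (CSF bright, WM dark), FLAIR (CSF suppressed, lesions
    bright).
    """
    return ContrastTable({
        "T1": {BACKGROUND: (0.02, 0.005), CSF: (0.12, 0.02), GM: (0.45, 0.03),
               WM: (0.68, 0.03), SKULL: (0.30, 0.04), LESION: (0.38, 0.03)},
        "T2": {BACKGROUND: (0.02, 0.005), CSF: (0.88, 0.02), GM: (0.55, 0.03),
               WM: (0.38, 0.03), SKULL: (0.25, 0.04), LESION: (0.75, 0.03)},
        "FLAIR": {BACKGROUND: (0.02, 0.005), CSF: (0.10, 0.02), GM: (0.55, 0.03),
                  WM: (0.42, 0.03), SKULL: (0.28, 0.04), LESION: (0.80, 0.03)},
    })


@dataclass
class DegradeSpec:
    """Parameters of the high-field -> ULF-like degradation.

    target_matrix : acquisition grid of the low-quality arm (each axis >= 8
        and <= the source grid).
    noise_sigma : additive noise scale on [0, 1] intensities.
    contrast_shrink : in [0, 1]; pulls in-brain intensities toward the
        in-brain mean (1 = all contrast removed).
    bias_amplitude : amplitude of the multiplicative low-frequency field.
    noise_model : ``"gaussian"`` or ``"rician"``.
    """

    target_matrix: tuple
    noise_sigma: float = 0.05
    contrast_shrink: float = 0.3
    bias_amplitude: float = 0.1
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        self.target_matrix = tuple(int(n) for n in self.target_matrix)
        if any(n < 8 for n in self.target_matrix):
            raise ValueError("target_matrix axes must be >= 8")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.contrast_shrink <= 1.0:
            raise ValueError("contrast_shrink must lie in [0, 1]")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def default_degrade_specs(grid) -> dict:
    """Per-contrast degradation specs with acquisition-matrix ratios scaled
    to the working grid (so a 64-cube phantom keeps the same downsample
    factors as the full-size acquisition geometry)."""
    grid = tuple(int(n) for n in grid)
    specs = {}
    for contrast, factors in _POC_FACTORS.items():
        target = tuple(max(8, min(n, round(n / f))) for n, f in zip(grid, factors))
        specs[contrast] = DegradeSpec(target_matrix=target)
    return specs


def _smooth_field(grid, rng: np.random.Generator, rel_sigma: float = 0.125) -> np.ndarray:
    """Zero-mean, unit-sd smooth random field (low-frequency)."""
    raw = rng.standard_normal(grid)
    smooth = ndimage.gaussian_filter(raw, sigma=max(1.0, rel_sigma * min(grid)))
    sd = smooth.std()
    if sd == 0:
        return np.zeros(grid)
    return (smooth - smooth.mean()) / sd


def make_label_map(grid=(64, 64, 64), deform_scale: float = 0.0,
                   lesion_count: int = 0, rng: np.random.Generator | None = None,
                   spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    """Nested ellipsoidal shells with smooth deformation and WM lesions.

    Deterministic given the rng seed.  ``deform_scale`` perturbs the
    normalized radius field (units of the head semi-axis; ~0.04 gives
    plausible anatomy-like irregularity).  Lesions are disjoint ellipsoidal
    blobs placed fully inside the white matter.
    """
    grid = tuple(int(n) for n in grid)
    if any(n < 32 for n in grid):
        raise ValueError(f"grid {grid} too small to fit the tissue shells (need >= 32 per axis)")
    if lesion_count < 0:
        raise ValueError("lesion_count must be >= 0")
    rng = np.random.default_rng(rng)

    center = [(n - 1) / 2.0 for n in grid]
    semi = [0.95 * (n - 1) / 2.0 for n in grid]
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid], indexing="ij")
    radius = np.sqrt(sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semi)))
    if deform_scale:
        radius = radius + deform_scale * _smooth_field(grid, rng)

    labels = np.zeros(grid, dtype=np.int16)
    # paint from the outermost shell inward so inner classes overwrite
    for lab, thr in reversed(_SHELLS):
        labels[radius < thr] = lab

    if lesion_count:
        labels = _add_lesions(labels, lesion_count, rng)
    return LabelMap(labels=labels, spacing=tuple(float(s) for s in spacing))


def _add_lesions(labels: np.ndarray, count: int, rng: np.random.Generator,
                 max_semiaxis: int = 4) -> np.ndarray:
    wm = labels == WM
    # erode so that a full lesion ellipsoid fits strictly inside WM
    interior = ndimage.binary_erosion(wm, iterations=max_semiaxis + 1)
    candidates = np.argwhere(interior)
    if candidates.size == 0:
        raise ValueError("white matter too thin to host lesions at this grid size")
    labels = labels.copy()
    centers: list[np.ndarray] = []
    min_sep = 2 * max_semiaxis + 2  # guarantees disjoint connected components
    attempts = 0
    while len(centers) < count:
        attempts += 1
        if attempts > 1000 * count:
            raise ValueError(f"could not place {count} disjoint lesions; grid too small")
        c = candidates[rng.integers(len(candidates))]
        if any(np.linalg.norm(c - p) < min_sep for p in centers):
            continue
        semis = rng.integers(2, max_semiaxis + 1, size=3)
        lo = [max(0, int(ci) - int(a)) for ci, a in zip(c, semis)]
        hi = [min(n, int(ci) + int(a) + 1) for ci, a, n in zip(c, semis, labels.shape)]
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        cc = np.meshgrid(*[np.arange(l, h, dtype=np.float64) for l, h in zip(lo, hi)], indexing="ij")
        ell = sum(((g - ci) / a) ** 2 for g, ci, a in zip(cc, c, semis)) <= 1.0
        region = labels[sub]
        region[ell & (region == WM)] = LESION
        centers.append(c)
    return labels


def synthesize_contrasts(label_map: LabelMap, table: ContrastTable,
                         rng: np.random.Generator | None = None) -> dict:
    """Per-contrast intensity volumes: label mean + label-sd Gaussian, clipped to [0, 1]."""
    rng = np.random.default_rng(rng)
    labels = label_map.labels
    present = np.unique(labels)
    out = {}
    for contrast in table.contrasts:
        entries = table.values[contrast]
        missing = [int(l) for l in present if int(l) not in entries]
        if missing:
            raise ValueError(f"contrast {contrast!r} lacks table entries for labels {missing}")
        max_label = int(present.max())
        means = np.zeros(max_label + 1)
        sds = np.zeros(max_label + 1)
        for lab, (m, s) in entries.items():
            if lab <= max_label:
                means[lab], sds[lab] = m, s
        img = means[labels] + sds[labels] * rng.standard_normal(labels.shape)
        out[contrast] = np.clip(img, 0.0, 1.0)
    return out


def degrade_to_ulf(volume, spacing, spec: DegradeSpec,
                   rng: np.random.Generator | None = None, mask=None) -> np.ndarray:
    """Produce the ULF-like arm of a pair, on the original grid.

    Pipeline: anti-aliased downsample to ``spec.target_matrix`` ->
    contrast shrink toward the in-brain mean -> multiplicative
    low-frequency bias field -> additive noise (gaussian or rician) ->
    trilinear upsample back to the source grid.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.min() < -1e-9 or volume.max() > 1.0 + 1e-9:
        raise ValueError("intensities must lie in [0, 1]")
    if any(t > n for t, n in zip(spec.target_matrix, volume.shape)):
        raise ValueError(f"target_matrix {spec.target_matrix} exceeds source grid {volume.shape}")
    rng = np.random.default_rng(rng)

    down = resize(volume, spec.target_matrix, order=1, mode="edge",
                  anti_aliasing=any(t < n for t, n in zip(spec.target_matrix, volume.shape)),
                  preserve_range=True)

    if spec.contrast_shrink > 0:
        if mask is None:
            from skimage.filters import threshold_otsu
            mask = volume > 0.5 * threshold_otsu(volume)
        mask_low = resize(np.asarray(mask, dtype=np.float64), spec.target_matrix,
                          order=1, mode="edge", anti_aliasing=False,
                          preserve_range=True) > 0.5
        if mask_low.any():
            mean = down[mask_low].mean()
            down[mask_low] = mean + (down[mask_low] - mean) * (1.0 - spec.contrast_shrink)

    if spec.bias_amplitude > 0:
        f = _smooth_field(spec.target_matrix, rng)
        peak = np.abs(f).max()
        if peak > 0:
            down = down * (1.0 + spec.bias_amplitude * f / peak)

    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            down = down + spec.noise_sigma * rng.standard_normal(down.shape)
        else:  # rician: magnitude of a complex signal with Gaussian noise
            n1 = rng.standard_normal(down.shape)
            n2 = rng.standard_normal(down.shape)
            down = np.sqrt((down + spec.noise_sigma * n1) ** 2 + (spec.noise_sigma * n2) ** 2)

    up = resize(down, volume.shape, order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    if not np.all(np.isfinite(up)):
        raise FloatingPointError("degradation produced non-finite values")
    return np.clip(up, 0.0, 1.0)


def make_paired_dataset(n_subjects: int, grid=(64, 64, 64), table: ContrastTable | None = None,
                        specs: dict | None = None, seed: int = 0, out_dir=".",
                        deform_scale: float = 0.04, lesion_count: int = 0,
                        spacing=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Write a fully reproducible paired dataset and return its manifest.

    Per subject: one label map, one brain mask, and one
    (conditioning, target) NIfTI pair per contrast.  Volumes are written
    uncompressed so re-runs with the same seed are byte-identical.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    table = table or default_contrast_table()
    specs = specs or default_degrade_specs(grid)
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    affine = np.diag(list(spacing) + [1.0])
    rows = []
    for i in range(n_subjects):
        subject_id = f"sub-{i:03d}"
        subj_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(subj_seed)
        lm = make_label_map(grid, deform_scale=deform_scale, lesion_count=lesion_count,
                            rng=rng, spacing=spacing)
        sub_dir = out_dir / subject_id
        sub_dir.mkdir(exist_ok=True)
        write_volume(lm.labels.astype(np.int16), spacing, affine, sub_dir / "labels.nii")
        mask = lm.brain_mask
        mask_path = sub_dir / "brain_mask.nii"
        write_volume(mask.astype(np.uint8), spacing, affine, mask_path)
        targets = synthesize_contrasts(lm, table, rng)
        for contrast in table.contrasts:
            target = targets[contrast]
            cond = degrade_to_ulf(target, spacing, specs[contrast], rng, mask=lm.head_mask)
            tgt_path = sub_dir / f"{contrast}_target.nii"
            cond_path = sub_dir / f"{contrast}_conditioning.nii"
            write_volume(target, spacing, affine, tgt_path)
            write_volume(cond, spacing, affine, cond_path)
            rows.append({
                "subject_id": subject_id, "contrast": contrast,
                "conditioning_path": str(cond_path), "target_path": str(tgt_path),
                "mask_path": str(mask_path), "seed": subj_seed,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
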