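"""Masked full-reference image-quality metrics and volumetric agreement.

PSNR, SSIM and MAE are computed inside a brain mask so that the large
empty background of a head volume cannot inflate similarity scores.  All
package volumes live on a [0, 1] intensity scale, so ``max_val`` defaults
to 1.0; pass it explicitly for any other range.

Masked SSIM convention: the local statistics use a uniform window of odd
size (default 7) with population (1/n) normalization, evaluated only at
centers whose window lies fully inside the image; the map is averaged over
centers that fall inside the mask.

Agreement between paired volumetric measurements follows Bland–Altman:
mean difference plus limits of agreement at mean +/- 1.96 sd (sample sd),
alongside the Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "mae",
    "psnr",
    "ssim",
    "metric_report",
    "region_volumes",
    "bland_altman",
    "pearson_r",
    "MetricReport",
    "AgreementReport",
]

CONTRASTS = ("T1", "T2", "FLAIR")


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match image shape {tuple(shape)}")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def mae(x, y, mask=None) -> float:
    """Mean absolute error over masked voxels: ``(1/N) sum |x_i - y_i|``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    m = _as_mask(mask, x.shape)
    return float(np.mean(np.abs(x[m] - y[m])))


def psnr(x, y, max_val: float = 1.0, mask=None) -> float:
    """Peak signal-to-noise ratio ``20 log10(MAX_I / sqrt(MSE))`` in dB.

    Identical images have zero MSE; that case returns ``math.inf`` (the
    documented sentinel), never a finite number.
    """
    if max_val <= 0:
        raise ValueError(f"max_val must be positive, got {max_val}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    m = _as_mask(mask, x.shape)
    mse = float(np.mean((x[m] - y[m]) ** 2))
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(max_val / math.sqrt(mse))


def _window_means(a: np.ndarray, size: int) -> np.ndarray:
    """Exact window means at all fully-interior centers (any ndim)."""
    full = ndimage.uniform_filter(a, size=size, mode="constant")
    r = size // 2
    sl = tuple(slice(r, n - r) for n in a.shape)
    return full[sl]


def ssim(x, y, window_size: int = 7, k1: float = 0.01, k2: float = 0.03,
         max_val: float = 1.0, mask=None) -> float:
    """Mean structural similarity over masked, fully-interior window centers.

    Per window: ``(2 mu_x mu_y + c1)(2 cov_xy + c2) /
    ((mu_x^2 + mu_y^2 + c1)(var_x + var_y + c2))`` with
    ``c1 = (k1 max_val)^2``, ``c2 = (k2 max_val)^2``.
    """
    if window_size % 2 == 0 or window_size < 1:
        raise ValueError(f"window_size must be odd and positive, got {window_size}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if any(n < window_size for n in x.shape):
        raise ValueError(f"window_size {window_size} exceeds image extent {x.shape}")
    m = _as_mask(mask, x.shape)

    mu_x = _window_means(x, window_size)
    mu_y = _window_means(y, window_size)
    var_x = _window_means(x * x, window_size) - mu_x**2
    var_y = _window_means(y * y, window_size) - mu_y**2
    cov = _window_means(x * y, window_size) - mu_x * mu_y

    c1 = (k1 * max_val) ** 2
    c2 = (k2 * max_val) ** 2
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    ssim_map = num / den

    r = window_size // 2
    interior = tuple(slice(r, n - r) for n in x.shape)
    m_interior = m[interior]
    if not m_interior.any():
        raise ValueError("mask contains no fully-interior window centers")
    return float(ssim_map[m_interior].mean())


@dataclass
class MetricReport:
    """Per-contrast PSNR (dB), SSIM and MAE plus the cross-contrast average."""

    per_contrast: dict
    average: dict
    n_voxels: int
    missing: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        rows = dict(self.per_contrast)
        rows["average"] = self.average
        return pd.DataFrame(rows).T[["psnr", "ssim", "mae"]]


def metric_report(pred_volumes: dict, ref_volumes: dict, mask,
                  max_val: float = 1.0, window_size: int = 7) -> MetricReport:
    """Masked PSNR/SSIM/MAE per contrast, then averaged across contrasts.

    Contrasts present in only one of the two dictionaries are skipped and
    recorded in ``missing``.
    """
    available = [c for c in pred_volumes if c in ref_volumes]
    missing = tuple(sorted(set(pred_volumes) ^ set(ref_volumes)))
    if not available:
        raise ValueError("no contrast is present in both pred and ref")
    per = {}
    for c in available:
        p, r = pred_volumes[c], ref_volumes[c]
        per[c] = {
            "psnr": psnr(p, r, max_val=max_val, mask=mask),
            "ssim": ssim(p, r, window_size=window_size, max_val=max_val, mask=mask),
            "mae": mae(p, r, mask=mask),
        }
    avg = {k: float(np.mean([per[c][k] for c in available])) for k in ("psnr", "ssim", "mae")}
    n_vox = int(np.sum(np.asarray(mask, dtype=bool))) if mask is not None \
        else int(np.prod(np.shape(next(iter(pred_volumes.values())))))
    return MetricReport(per_contrast=per, average=avg, n_voxels=n_vox, missing=missing)


def region_volumes(label_map, spacing) -> pd.Series:
    """Volume in mm^3 per nonzero label: voxel count times voxel volume."""
    labels = np.asarray(label_map)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label map must be integer-valued")
    spacing = np.asarray(spacing, dtype=np.float64)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    voxel_mm3 = float(np.prod(spacing))
    counts = np.bincount(labels.ravel())
    idx = np.nonzero(counts)[0]
    idx = idx[idx > 0]
    return pd.Series(counts[idx] * voxel_mm3, index=idx, name="volume_mm3")


@dataclass
class AgreementReport:
    """Bland–Altman summary of paired measurements (a - b differences)."""

    mean_difference: float
    loa_low: float
    loa_high: float
    pearson_r: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_difference <= self.loa_high):
            raise ValueError("limits of agreement must bracket the mean difference")


def pearson_r(a, b) -> float:
    """Pearson correlation; ``nan`` sentinel when either series is constant."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and equal length")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return math.nan
    return float(stats.pearsonr(a, b).statistic)


def bland_altman(a, b, loa_multiplier: float = 1.96) -> AgreementReport:
    """Limits of agreement ``mean(d) +/- 1.96 sd(d)`` for ``d = a - b``."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and equal length")
    if a.size < 3:
        raise ValueError(f"need at least 3 paired values, got {a.size}")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        mean_difference=md,
        loa_low=md - loa_multiplier * sd,
        loa_high=md + loa_multiplier * sd,
        pearson_r=pearson_r(a, b) if (np.std(a) and np.std(b)) else (1.0 if np.allclose(a, b) else math.nan),
        n=int(a.size),
    )
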