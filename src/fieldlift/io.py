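"""NIfTI volume I/O and the paired-volume container.

Volumes are stored as float32 NIfTI-1; reading back reproduces data,
spacing and affine bit-exactly.  Dataset manifests are plain CSV tables
with one row per (subject, contrast) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["VolumePair", "read_volume", "write_volume", "read_manifest", "load_pair"]

MANIFEST_COLUMNS = ["subject_id", "contrast", "conditioning_path", "target_path", "mask_path", "seed"]


class VolumeReadError(ValueError):
    """Raised when a file cannot be parsed as a NIfTI volume."""


@dataclass
class VolumePair:
    """Co-registered conditioning (low-quality) and target (high-quality) volumes.

    Both arrays live on the same grid with the same spacing; intensities are
    on a [0, 1] scale.  ``brain_mask`` marks in-brain voxels for the masked
    metrics.
    """

    conditioning: np.ndarray
    target: np.ndarray
    spacing: tuple
    contrast: str
    brain_mask: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.conditioning.shape != self.target.shape:
            raise ValueError("conditioning and target must share a grid")
        if self.brain_mask.shape != self.target.shape:
            raise ValueError("brain_mask must share the volume grid")
        if not (np.all(np.isfinite(self.conditioning)) and np.all(np.isfinite(self.target))):
            raise ValueError("volumes contain non-finite intensities")
        if not np.any(self.brain_mask):
            raise ValueError("brain_mask is empty")


def write_volume(array, spacing, affine, path) -> Path:
    """Write a float32 NIfTI-1 volume; returns the path written."""
    array = np.asarray(array, dtype=np.float32)
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(array, np.asarray(affine, dtype=np.float64))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    img.header.set_data_dtype(np.float32)
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_volume(path):
    """Read a NIfTI volume; returns ``(array, spacing, affine)``.

    Malformed files raise :class:`VolumeReadError`.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of parse errors
        raise VolumeReadError(f"cannot read {path!r} as NIfTI: {exc}") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return data, spacing, np.asarray(img.affine)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path!r} lacks columns {missing}")
    return df


def load_pair(row) -> VolumePair:
    """Materialize a VolumePair from one manifest row."""
    cond, spacing, _ = read_volume(row["conditioning_path"])
    tgt, _, _ = read_volume(row["target_path"])
    mask, _, _ = read_volume(row["mask_path"])
    return VolumePair(
        conditioning=np.asarray(cond, dtype=np.float32),
        target=np.asarray(tgt, dtype=np.float32),
        spacing=spacing,
        contrast=str(row["contrast"]),
        brain_mask=np.asarray(mask) > 0.5,
        subject_id=str(row["subject_id"]),
    )
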