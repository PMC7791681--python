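"""BOLD signal-variability (SV) maps: temporal SD and whole-mask z-scores.

The per-subject statistic is the sample standard deviation over time of each
voxel's (preprocessed, band-limited) series, standardised across a
gray-matter mask: z = (SD - mean_mask) / SD_mask.  A positive z means the
voxel fluctuates more than the gray-matter average for that subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BandSpec
from .volume import Volume4D, grid_centers_mm

__all__ = ["SvMap", "compute_sv", "standardize_sv", "extract_peak_sv"]


@dataclass
class SvMap:
    """Per-subject variability map: raw SD, its z-standardised form, the mask."""

    raw_sd: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    band: BandSpec | None = None


def compute_sv(vol: Volume4D, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel sample SD over time (denominator T-1).

    Invariant to time reversal and to adding a constant to any series.
    """
    if vol.n_volumes < 2:
        raise ValueError("need T >= 2 to compute a temporal SD")
    if mask is not None and not np.any(mask):
        raise ValueError("mask is empty")
    return vol.data.std(axis=-1, ddof=1)


def standardize_sv(raw_sd: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-standardise a raw SD map over the gray-matter mask.

    z = (raw_sd - mean over mask) / (sample SD over mask); values outside the
    mask are set to 0.  By construction the in-mask z values have mean 0 and
    sample SD 1.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = raw_sd[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    mu = vals.mean()
    sd = vals.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("degenerate image: zero SD spread across the mask")
    z = np.zeros_like(raw_sd, dtype=float)
    z[mask] = (vals - mu) / sd
    return z


def sv_map(vol: Volume4D, mask: np.ndarray, band: BandSpec | None = None) -> SvMap:
    """Convenience: raw SD + z map bundle for one subject."""
    raw = compute_sv(vol, mask)
    return SvMap(raw_sd=raw, z=standardize_sv(raw, mask), mask=np.asarray(mask, bool), band=band)


def extract_peak_sv(
    z: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    center_mm,
    radius_mm: float = 3.0,
) -> float:
    """Mean z over in-mask voxels within ``radius_mm`` of a world-mm center.

    Sphere membership is by voxel-center Euclidean distance in world mm
    (affine-aware), inclusive boundary.
    """
    mask = np.asarray(mask, dtype=bool)
    centers = grid_centers_mm(z.shape, affine)
    dist = np.linalg.norm(centers - np.asarray(center_mm, dtype=float), axis=-1)
    sel = (dist <= radius_mm) & mask
    if not np.any(sel):
        raise ValueError(
            f"sphere at {tuple(center_mm)} (r={radius_mm} mm) contains no in-mask voxels"
        )
    return float(z[sel].mean())
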