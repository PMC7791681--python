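"""Preprocessing tail for resting-state runs already aligned to a common grid.

Covers initial-volume discard, grand-mean scaling, nuisance + polynomial-trend
regression, spatial Gaussian smoothing, ideal FFT band-pass filtering into the
overall low-frequency band and the canonical slow-5/4/3 sub-bands, and
framewise-displacement motion QC.  Head-motion estimation, slice timing and
spatial normalisation are out of scope: motion parameters are consumed, never
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume4D

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "discard_initial_volumes",
    "grand_mean_scale",
    "regress_nuisance",
    "smooth_gaussian",
    "bandpass",
    "bandpass_series",
    "framewise_displacement",
]


@dataclass(frozen=True)
class BandSpec:
    """A temporal frequency band in Hz.

    Band membership is half-open, ``low < f <= high``, so that adjacent
    sub-bands are disjoint and tile their union exactly; the DC component is
    never retained.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high):
            raise ValueError(f"band {self.name!r}: need 0 <= low < high, got [{self.low}, {self.high}]")


#: The four analysis bands: overall low-frequency range and slow-5/4/3.
DEFAULT_BANDS: dict[str, BandSpec] = {
    "overall": BandSpec("overall", 0.01, 0.198),
    "slow5": BandSpec("slow5", 0.01, 0.027),
    "slow4": BandSpec("slow4", 0.027, 0.073),
    "slow3": BandSpec("slow3", 0.073, 0.198),
}


def discard_initial_volumes(vol: Volume4D, k: int = 5) -> Volume4D:
    """Drop the first ``k`` volumes (scanner equilibration period)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= vol.n_volumes:
        raise ValueError(f"cannot discard {k} of {vol.n_volumes} volumes")
    if k == 0:
        return vol.with_data(vol.data.copy())
    return vol.with_data(vol.data[..., k:].copy())


def grand_mean_scale(vol: Volume4D, target: float = 10000.0, mask=None) -> Volume4D:
    """Rescale so the 4D mean (over mask if given) equals ``target``.

    A per-subject multiplicative normalisation; it cancels in the
    z-standardised variability map but is kept for fidelity to the usual
    resting-state stream.
    """
    data = vol.data[mask] if mask is not None else vol.data
    mean = float(np.mean(data))
    if abs(mean) < 1e-12:
        raise ValueError("grand mean is zero; cannot scale")
    return vol.with_data(vol.data * (target / mean))


def _trend_design(n_time: int, nuisance: np.ndarray | None, detrend: bool) -> np.ndarray:
    cols = [np.ones(n_time)]
    if detrend:
        t = np.linspace(-1.0, 1.0, n_time)
        cols += [t, t**2]
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.ndim == 1:
            nuisance = nuisance[:, None]
        if nuisance.shape[0] != n_time:
            raise ValueError(
                f"nuisance table has {nuisance.shape[0]} rows, image has {n_time} volumes"
            )
        cols += [nuisance[:, j] for j in range(nuisance.shape[1])]
    return np.column_stack(cols)


def regress_nuisance(
    vol: Volume4D,
    nuisance: np.ndarray | None = None,
    detrend: bool = True,
) -> Volume4D:
    """Residualise every voxel series against nuisance and trend regressors.

    The design is [intercept, linear, quadratic (if ``detrend``), nuisance
    columns]; each voxel series is replaced by its least-squares residual,
    which is orthogonal to every regressor.  Typical nuisance columns are the
    CSF and white-matter mean signals plus six rigid-body motion parameters.
    """
    shape = vol.data.shape
    n_time = shape[3]
    X = _trend_design(n_time, nuisance, detrend)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the pivoted-QR R diagonal
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(piv[rank:].tolist())
        raise ValueError(
            f"rank-deficient nuisance design (rank {rank} < {X.shape[1]}); "
            f"dependent column indices: {bad}"
        )
    q, _ = np.linalg.qr(X)
    flat = vol.data.reshape(-1, n_time).T  # (T, V)
    resid = flat - q @ (q.T @ flat)
    return vol.with_data(resid.T.reshape(shape))


def smooth_gaussian(vol: Volume4D, fwhm_mm: float = 6.0) -> Volume4D:
    """Spatially smooth each volume with a Gaussian kernel of given FWHM (mm).

    Sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` divided by that axis's voxel
    size, so anisotropic voxels are handled.  The boundary mode is symmetric
    ('reflect') extension, which preserves constant images and conserves the
    spatial mean exactly.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    voxel = vol.voxel_sizes
    if np.any(voxel <= 0):
        raise ValueError(f"non-positive voxel size from affine: {voxel}")
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / voxel
    out = ndimage.gaussian_filter(
        vol.data, sigma=tuple(sigma_vox) + (0.0,), mode="reflect"
    )
    return vol.with_data(out)


def _band_gain(n_time: int, tr: float, band: BandSpec) -> np.ndarray:
    nyq = 1.0 / (2.0 * tr)
    if band.high > nyq + 1e-12:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz exceeds the Nyquist "
            f"frequency {nyq:.6g} Hz for TR={tr}s"
        )
    freqs = np.fft.rfftfreq(n_time, d=tr)
    return (freqs > band.low) & (freqs <= band.high)


def bandpass_series(x: np.ndarray, tr: float, band: BandSpec, axis: int = -1) -> np.ndarray:
    """Zero-phase ideal (brick-wall) FFT band-pass along ``axis``.

    Fourier coefficients with ``low < f <= high`` are retained; everything
    else, including DC, is zeroed, so the output has (numerically) zero mean.
    Half-open membership keeps the slow-5/4/3 sub-bands disjoint while their
    union reproduces the overall band exactly (Parseval variance partition).
    """
    x = np.asarray(x, dtype=float)
    n_time = x.shape[axis]
    gain = _band_gain(n_time, tr, band)
    spec = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = gain.size
    spec = spec * gain.reshape(shape)
    return np.fft.irfft(spec, n=n_time, axis=axis)


def bandpass(vol: Volume4D, band: BandSpec) -> Volume4D:
    """Band-pass every voxel time series (see :func:`bandpass_series`)."""
    return vol.with_data(bandpass_series(vol.data, vol.tr, band, axis=-1))


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Framewise displacement from a T x 6 motion table (Power convention).

    Columns are three translations in mm then three rotations in radians;
    FD_t is the sum of absolute backward differences, rotations converted to
    arc length on a sphere of ``head_radius_mm``.  FD_0 is defined as 0.

    Returns
    -------
    (fd, mean_fd) : length-T array and its mean.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must be T x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 time points for framewise displacement")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return fd, float(fd.mean())
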