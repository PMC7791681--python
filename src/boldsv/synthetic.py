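"""Synthetic cohorts with known ground truth for every pipeline stage.

Generates 4D runs of band-limited Gaussian noise with planted group
differences in temporal SD, smooth random-walk motion traces, nuisance
signal tables, ROI-pair series from an exact ARMA(1,1)+GARCH(1,1)+DCC(1,1)
generative process, and clinical tables with a controlled rank association.
All planted effects are recorded so downstream stages have recovery targets.

Emulated acquisition: 240 volumes at TR = 2 s on a 2-mm isotropic grid by
default.  Not emulated: hemodynamic response shape, physiological
(cardiac/respiratory) waveforms, scanner artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volume import Volume4D, mni_like_affine, grid_centers_mm

__all__ = [
    "EffectBlob",
    "SyntheticCohortConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "simulate_cohort",
    "DccGenParams",
    "simulate_dcc_pair",
    "simulate_clinical_table",
]


@dataclass(frozen=True)
class EffectBlob:
    """A spherical region where group B's time-series SD is multiplied."""

    center_vox: tuple[int, int, int]
    radius_mm: float
    multiplier: float

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("EffectBlob.radius_mm must be positive")
        if not self.multiplier > 0:
            raise ValueError("EffectBlob.multiplier must be positive")


@dataclass
class SyntheticCohortConfig:
    """Study-condition parameters for a synthetic two-group cohort.

    Defaults emulate the study conditions: 26 controls vs 20 patients,
    240 volumes at TR = 2 s, 2-mm isotropic voxels.
    """

    n_group_a: int = 26
    n_group_b: int = 20
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size: float = 2.0
    tr: float = 2.0
    n_volumes: int = 240
    effect_blobs: list[EffectBlob] = field(default_factory=list)
    noise_band: tuple[float, float] = (0.01, 0.25)
    motion_scale: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 10:
            raise ValueError("n_volumes must be >= 10")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        low, high = self.noise_band
        nyq = 1.0 / (2.0 * self.tr)
        if not (0.0 <= low < high <= nyq + 1e-12):
            raise ValueError(f"noise_band must satisfy 0 <= low < high <= Nyquist ({nyq:g} Hz)")
        if self.motion_scale < 0:
            raise ValueError("motion_scale must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        return mni_like_affine(self.grid_shape, self.voxel_size)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str  # "A" (e.g. controls) or "B" (e.g. patients)
    volume: Volume4D
    motion: pd.DataFrame
    nuisance: pd.DataFrame


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    subjects: list[SyntheticSubject]
    effect_mask: np.ndarray
    gm_mask: np.ndarray

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]


_MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _band_limited_noise(rng, shape, tr, band):
    """White Gaussian noise FFT-filtered to ``band`` and rescaled to unit SD.

    Each series is rescaled to sample SD exactly 1 so planted multiplicative
    effects carry through to the empirical SD map exactly.
    """
    low, high = band
    T = shape[-1]
    x = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(T, d=tr)
    gain = (freqs > low) & (freqs <= high)
    gain[0] = False
    spec = np.fft.rfft(x, axis=-1) * gain
    x = np.fft.irfft(spec, n=T, axis=-1)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _effect_mask(config: SyntheticCohortConfig) -> np.ndarray:
    mask = np.zeros(config.grid_shape, dtype=bool)
    centers = grid_centers_mm(config.grid_shape, config.affine)
    for blob in config.effect_blobs:
        c = centers[tuple(blob.center_vox)]
        mask |= np.linalg.norm(centers - c, axis=-1) <= blob.radius_mm
    return mask


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # fixed per-subject stream offsets: cohorts reproduce under subsetting
    return np.random.default_rng([int(seed), int(index)])


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a two-group cohort of 4D runs with planted SD effects.

    Every voxel series is band-limited Gaussian noise with sample SD exactly
    1; voxels inside an effect blob have their series multiplied by the
    blob's SD multiplier for group B subjects only.  Motion tables are
    Gaussian random walks (rotation increments scaled by 1/50 so their
    arc-length FD contribution matches the translations); nuisance tables
    carry CSF and WM noise series.  Identical seeds give bit-identical
    cohorts.
    """
    affine = config.affine
    effect = _effect_mask(config)
    gm_mask = np.ones(config.grid_shape, dtype=bool)
    t_steps = config.n_volumes
    subjects: list[SyntheticSubject] = []
    n_total = config.n_group_a + config.n_group_b
    for idx in range(n_total):
        group = "A" if idx < config.n_group_a else "B"
        rng = _subject_rng(config.seed, idx)
        data = _band_limited_noise(
            rng, config.grid_shape + (t_steps,), config.tr, config.noise_band
        )
        if group == "B":
            for blob in config.effect_blobs:
                centers = grid_centers_mm(config.grid_shape, affine)
                c = centers[tuple(blob.center_vox)]
                sel = np.linalg.norm(centers - c, axis=-1) <= blob.radius_mm
                data[sel] *= blob.multiplier
        data += 100.0  # baseline intensity; removed by detrending downstream
        inc_sd = config.motion_scale / np.sqrt(t_steps)
        inc = rng.normal(0.0, inc_sd, size=(t_steps, 6))
        inc[:, 3:] /= 50.0  # radians; arc on a 50-mm sphere matches translations
        motion = pd.DataFrame(np.cumsum(inc, axis=0), columns=_MOTION_COLS)
        nuis = _band_limited_noise(rng, (2, t_steps), config.tr, config.noise_band)
        nuisance = pd.DataFrame(nuis.T, columns=["csf", "wm"])
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{idx:03d}",
                group=group,
                volume=Volume4D(data=data, affine=affine, tr=config.tr),
                motion=motion,
                nuisance=nuisance,
            )
        )
    return SyntheticCohort(config=config, subjects=subjects, effect_mask=effect, gm_mask=gm_mask)


# ---------------------------------------------------------------------------
# Generative twin of the ARMA+GARCH+DCC estimation stack
# ---------------------------------------------------------------------------


@dataclass
class DccGenParams:
    """Ground-truth parameters for a simulated ROI pair.

    Per-series ARMA(1,1) mean equation (c, phi, theta), GARCH(1,1) variance
    equation (omega, alpha, beta), DCC(1,1) correlation dynamics (a, b) with
    unconditional correlation rho_bar.
    """

    c: float = 0.0
    phi: float = 0.3
    theta: float = 0.1
    omega: float = 0.05
    alpha: float = 0.05
    beta: float = 0.90
    a: float = 0.05
    b: float = 0.90
    rho_bar: float = 0.4
    n_obs: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("omega",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha", "beta", "a", "b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.alpha + self.beta >= 1:
            raise ValueError("alpha + beta must be < 1 (covariance stationarity)")
        if self.a + self.b >= 1:
            raise ValueError("a + b must be < 1 (DCC stationarity)")
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1")
        if not -1 < self.rho_bar < 1:
            raise ValueError("rho_bar must be in (-1, 1)")
        if self.n_obs < 2:
            raise ValueError("n_obs must be >= 2")


def simulate_dcc_pair(params: DccGenParams, burn: int = 250):
    """Simulate two series from the exact ARMA+GARCH+DCC recursions.

    Returns
    -------
    (x, R_true, sigma_true) : x is (T, 2); R_true the true conditional
    correlation path; sigma_true the (T, 2) true conditional SD paths.
    With a = b = 0 the true R_t is constant at rho_bar.
    """
    rng = np.random.default_rng(params.seed)
    T = params.n_obs + burn
    rho = params.rho_bar
    qbar11 = qbar22 = 1.0
    qbar12 = rho
    a, b = params.a, params.b
    p11, p12, p22 = qbar11, qbar12, qbar22
    sigma2 = np.full(2, params.omega / (1.0 - params.alpha - params.beta))
    u_prev = np.zeros(2)
    x_prev = np.full(2, params.c / (1.0 - params.phi))
    xs = np.empty((T, 2))
    Rs = np.empty(T)
    sig = np.empty((T, 2))
    z = rng.standard_normal((T, 2))
    for t in range(T):
        r = p12 / np.sqrt(p11 * p22)
        r = float(np.clip(r, -0.9999, 0.9999))
        Rs[t] = r
        eta1 = z[t, 0]
        eta2 = r * z[t, 0] + np.sqrt(1.0 - r * r) * z[t, 1]
        eta = np.array([eta1, eta2])
        s = np.sqrt(sigma2)
        sig[t] = s
        u = s * eta
        x = params.c + params.phi * x_prev + u + params.theta * u_prev
        xs[t] = x
        # recursions for t+1
        p11 = (1 - a - b) * qbar11 + a * eta[0] * eta[0] + b * p11
        p12 = (1 - a - b) * qbar12 + a * eta[0] * eta[1] + b * p12
        p22 = (1 - a - b) * qbar22 + a * eta[1] * eta[1] + b * p22
        sigma2 = params.omega + params.alpha * u**2 + params.beta * sigma2
        u_prev = u
        x_prev = x
    return xs[burn:], Rs[burn:], sig[burn:]


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


def simulate_clinical_table(
    n: int,
    seed: int = 0,
    rho_target: float = 0.0,
    covariate: np.ndarray | None = None,
) -> pd.DataFrame:
    """Clinical table with a controlled Spearman association.

    The craniofacial pain score percentage (P.A.I.N.S. %) is generated via a
    Gaussian copula against ``covariate`` (supplied or generated) with latent
    Pearson r = 2 sin(pi rho_target / 6), so the population Spearman rho of
    the pair equals rho_target; monotone transforms to the reporting scale
    preserve it.  Columns: group, age, sex, pains_pct, vas, threshold_c,
    covariate.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("|rho_target| must be <= 1")
    rng = np.random.default_rng(seed)
    if covariate is None:
        covariate = rng.standard_normal(n)
    covariate = np.asarray(covariate, dtype=float).ravel()
    if covariate.size != n:
        raise ValueError("covariate length must equal n")
    # normal scores of the covariate ranks drive the copula
    ranks = stats.rankdata(covariate, method="average")
    zx = stats.norm.ppf(ranks / (n + 1.0))
    zx = (zx - zx.mean()) / (zx.std() or 1.0)
    r_latent = 2.0 * np.sin(np.pi * rho_target / 6.0)
    zy = r_latent * zx + np.sqrt(max(1.0 - r_latent**2, 0.0)) * rng.standard_normal(n)
    # monotone map to a plausible 0-100% scale centred near mild severity
    pains_pct = 100.0 * stats.norm.cdf(zy - 1.1)
    return pd.DataFrame(
        {
            "group": ["B"] * n,
            "age": np.clip(rng.normal(28.5, 7.0, n), 18, 45).round(1),
            "sex": rng.choice(["F", "M"], size=n, p=[0.7, 0.3]),
            "pains_pct": pains_pct,
            "vas": np.clip(rng.normal(4.7, 2.2, n), 0, 10).round(1),
            "threshold_c": np.clip(rng.normal(43.1, 4.4, n), 32, 50).round(1),
            "covariate": covariate,
        }
    )
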