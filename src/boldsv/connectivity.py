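"""ROI cross-correlation and DCC-GARCH dynamic functional connectivity.

The dynamic-connectivity stack follows the standard two-stage quasi-maximum
likelihood route:

1. each ROI mean time series is pre-whitened with an ARMA(1,1) mean model;
2. a GARCH(1,1) variance model is fitted to the ARMA innovations and the
   innovations are standardised by the conditional SD;
3. the pair of standardised residual series enters a DCC(1,1) correlation
   recursion Q_t = (1-a-b) Qbar + a e_{t-1} e_{t-1}' + b Q_{t-1}, whose
   normalised off-diagonal R_t is the time-varying correlation; an
   exponentially-weighted moving average (fixed decay) mode is available as
   the a+b -> 1 limiting alternative.

dFC strength and variability are the time mean and sample SD of R_t.

The model-fitting surface is statsmodels-style: ``ArmaGarchModel(x).fit()``
and ``DCCModel(e1, e2).fit()`` return results objects carrying estimates,
paths, convergence diagnostics and a ``summary()``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .preprocess import BandSpec, DEFAULT_BANDS, bandpass
from .variability import extract_peak_sv  # noqa: F401  (re-export convenience)
from .volume import Volume4D, grid_centers_mm

logger = logging.getLogger(__name__)

__all__ = [
    "RoiSpec",
    "DEFAULT_SEEDS",
    "DEFAULT_PAIRS",
    "extract_roi_series",
    "cross_correlation",
    "ArmaGarchModel",
    "ArmaGarchResults",
    "DCCModel",
    "DCCResults",
    "fit_arma_garch",
    "fit_dcc",
    "dfc_summaries",
    "compare_dfc",
    "garch_sigma2_path",
]


@dataclass(frozen=True)
class RoiSpec:
    """A spherical seed region: name, world-mm center, radius."""

    name: str
    center: tuple[float, float, float]
    radius: float = 5.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")


#: Default seed set: peak coordinates of the group-difference clusters in the
#: trigeminal spinal-thalamo-cortical and frontoparietal pathways.
DEFAULT_SEEDS: dict[str, RoiSpec] = {
    "SpV_R": RoiSpec("SpV_R", (8.0, -36.0, -52.0)),
    "PuM_L": RoiSpec("PuM_L", (-12.0, -30.0, 10.0)),
    "VPM_L": RoiSpec("VPM_L", (-12.0, -20.0, -2.0)),
    "dpINS_L": RoiSpec("dpINS_L", (-38.0, -24.0, 16.0)),
    "S1_L": RoiSpec("S1_L", (-46.0, -30.0, 60.0)),
    "dlPFC_R": RoiSpec("dlPFC_R", (44.0, 22.0, 36.0)),
    "IPC_R": RoiSpec("IPC_R", (38.0, -54.0, 44.0)),
}

#: ROI pairs analysed for dynamic connectivity (ascending pathway + frontoparietal).
DEFAULT_PAIRS: list[tuple[str, str]] = [
    ("SpV_R", "VPM_L"),
    ("VPM_L", "dpINS_L"),
    ("VPM_L", "S1_L"),
    ("dlPFC_R", "IPC_R"),
]


def extract_roi_series(
    vol: Volume4D, roi: RoiSpec, band: BandSpec | None = DEFAULT_BANDS["overall"]
) -> np.ndarray:
    """Mean band-filtered time series over the in-sphere voxels of a seed."""
    if band is not None:
        vol = bandpass(vol, band)
    centers = grid_centers_mm(vol.data.shape[:3], vol.affine)
    dist = np.linalg.norm(centers - np.asarray(roi.center, dtype=float), axis=-1)
    sel = dist <= roi.radius
    if not sel.any():
        raise ValueError(f"ROI {roi.name!r} at {roi.center} does not intersect the image")
    return vol.data[sel].mean(axis=0)


def cross_correlation(x, y, max_lag: int = 20):
    """Normalised cross-correlation at lags -max_lag..+max_lag.

    r(k) for k >= 0 correlates x_t with y_{t+k}; normalisation uses
    full-series means and SDs so the lag-0 value equals the Pearson
    correlation.  Returns (lags, ccf, bound) with the approximate 95%
    confidence bound 1.96/sqrt(T) for white-noise inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D series")
    T = x.size
    if T <= max_lag:
        raise ValueError("series shorter than max_lag")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float((dx**2).sum() * (dy**2).sum()))
    if denom == 0:
        raise ValueError("zero-variance input")
    lags = np.arange(-max_lag, max_lag + 1)
    ccf = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            ccf[i] = float((dx[: T - k] * dy[k:]).sum()) / denom
        else:
            ccf[i] = float((dx[-k:] * dy[: T + k]).sum()) / denom
    return lags, ccf, 1.96 / math.sqrt(T)


# ---------------------------------------------------------------------------
# ARMA(1,1) + GARCH(1,1) pre-whitening
# ---------------------------------------------------------------------------


def _arma_innovations(x: np.ndarray, c: float, phi: float, theta: float) -> np.ndarray:
    """Innovation recursion e_t = x_t - c - phi x_{t-1} - theta e_{t-1}, e_0 = 0.

    Conditions on x_0; the returned array has length T with e[0] = 0.
    """
    T = x.size
    e = np.zeros(T)
    prev_e = 0.0
    xs = x  # local alias
    for t in range(1, T):
        prev_e = xs[t] - c - phi * xs[t - 1] - theta * prev_e
        e[t] = prev_e
    return e


def garch_sigma2_path(
    eps: np.ndarray,
    omega: float,
    alpha: float,
    beta: float,
    sigma2_0: float | None = None,
) -> np.ndarray:
    """Conditional-variance recursion sigma2_t = omega + alpha eps_{t-1}^2 + beta sigma2_{t-1}.

    sigma2_0 defaults to the sample variance of ``eps`` (the standard
    initialisation); results at small T are sensitive to this choice.
    """
    eps = np.asarray(eps, dtype=float)
    T = eps.size
    if sigma2_0 is None:
        sigma2_0 = float(eps.var())
    s = np.empty(T)
    s[0] = sigma2_0
    prev = sigma2_0
    for t in range(1, T):
        prev = omega + alpha * eps[t - 1] ** 2 + beta * prev
        s[t] = prev
    return s


def _garch_negll(params, eps, sigma2_0):
    omega, alpha, beta = params
    s = garch_sigma2_path(eps, omega, alpha, beta, sigma2_0)
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        return 1e12
    return 0.5 * float(np.sum(np.log(s) + eps**2 / s))


def _unpack_garch(p):
    """Unconstrained -> (omega, alpha, beta) with omega > 0, alpha+beta < 1."""
    p = np.clip(p, -35.0, 35.0)  # keep exp/logistic finite under optimizer excursions
    omega = math.exp(p[0])
    ab = 0.999 / (1.0 + math.exp(-p[1]))
    frac = 1.0 / (1.0 + math.exp(-p[2]))
    return omega, ab * frac, ab * (1.0 - frac)


@dataclass
class ArmaGarchResults:
    """Fitted ARMA(1,1)+GARCH(1,1) pre-whitening for one series."""

    c: float
    phi: float
    theta: float
    omega: float
    alpha: float
    beta: float
    sigma_t: np.ndarray
    std_resid: np.ndarray
    resid: np.ndarray
    loglik: float
    converged: bool
    fallback_constant_variance: bool = False
    nobs: int = 0

    @property
    def persistence(self) -> float:
        """GARCH persistence alpha + beta (< 1 for covariance stationarity)."""
        return self.alpha + self.beta

    def summary(self) -> str:
        lines = [
            "ARMA(1,1)-GARCH(1,1) pre-whitening",
            f"  nobs           {self.nobs}",
            f"  mean eq.       c={self.c:+.4f}  phi={self.phi:+.4f}  theta={self.theta:+.4f}",
            f"  variance eq.   omega={self.omega:.4g}  alpha={self.alpha:.4f}  beta={self.beta:.4f}",
            f"  persistence    {self.persistence:.4f}",
            f"  loglik         {self.loglik:.3f}",
            f"  converged      {self.converged}"
            + ("  [fallback: constant variance]" if self.fallback_constant_variance else ""),
        ]
        return "\n".join(lines)


class ArmaGarchModel:
    """Two-stage ARMA(1,1) mean + GARCH(1,1) variance model for one series.

    Stage 1 estimates (c, phi, theta) by Gaussian conditional MLE (equivalent
    to minimising the innovation sum of squares); stage 2 estimates (omega,
    alpha, beta) by quasi-MLE on the innovations with the variance recursion
    initialised at their sample variance.  Optimisation is bounded
    quasi-Newton on transformed parameters (log omega; logistic alpha/beta
    with the stationarity sum enforced by reparameterisation) with three
    starts.  Non-convergence is flagged, not raised; the fallback
    standardises by the constant sample SD.
    """

    def __init__(self, x, min_nobs: int = 50):
        x = np.asarray(x, dtype=float).ravel()
        if x.size < min_nobs:
            raise ValueError(f"series too short: {x.size} < {min_nobs}")
        if not np.all(np.isfinite(x)):
            raise ValueError("series contains non-finite values")
        self.x = x

    def _fit_arma(self):
        x = self.x
        # moment-based starting values
        xc = x - x.mean()
        denom = float((xc**2).sum())
        r1 = float((xc[:-1] * xc[1:]).sum()) / denom if denom > 0 else 0.0
        starts = [(r1, 0.0), (0.5, 0.0), (0.0, 0.3)]
        best = None
        for phi0, theta0 in starts:
            p0 = np.array([x.mean() * (1 - phi0), phi0, theta0])

            def sse(p):
                e = _arma_innovations(x, p[0], np.clip(p[1], -0.999, 0.999), np.clip(p[2], -0.999, 0.999))
                return float((e[1:] ** 2).sum())

            res = optimize.minimize(
                sse,
                p0,
                method="L-BFGS-B",
                bounds=[(None, None), (-0.99, 0.99), (-0.99, 0.99)],
            )
            if best is None or res.fun < best.fun:
                best = res
        c, phi, theta = best.x
        return float(c), float(phi), float(theta), bool(best.success)

    def fit(self) -> ArmaGarchResults:
        x = self.x
        c, phi, theta, arma_ok = self._fit_arma()
        eps = _arma_innovations(x, c, phi, theta)
        eps = eps - 0.0  # innovations; e_0 = 0 by convention
        sigma2_0 = float(eps[1:].var()) if eps.size > 2 else float(eps.var())
        if sigma2_0 <= 0:
            sigma2_0 = 1e-8
        v = sigma2_0
        starts = [(0.05, 0.90), (0.10, 0.80), (0.20, 0.50)]
        best = None
        for a0, b0 in starts:
            w0 = max(v * (1 - a0 - b0), 1e-8)
            p0 = np.array(
                [
                    math.log(w0),
                    math.log((a0 + b0) / (0.999 - (a0 + b0))),
                    math.log(a0 / b0),
                ]
            )
            res = optimize.minimize(
                lambda p: _garch_negll(_unpack_garch(p), eps, sigma2_0),
                p0,
                method="Nelder-Mead",
                options={"maxiter": 600, "xatol": 1e-6, "fatol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        omega, alpha, beta = _unpack_garch(best.x)
        garch_ok = bool(best.success) and np.isfinite(best.fun)
        converged = arma_ok and garch_ok
        fallback = False
        if not garch_ok or omega <= 0 or alpha + beta >= 0.999:
            # constant-variance standardisation fallback
            logger.warning("GARCH fit did not converge; using constant-variance fallback")
            fallback = True
            omega, alpha, beta = sigma2_0, 0.0, 0.0
        sigma_t = np.sqrt(garch_sigma2_path(eps, omega, alpha, beta, sigma2_0))
        std_resid = eps / sigma_t
        loglik = -_garch_negll((omega, alpha, beta), eps, sigma2_0)
        return ArmaGarchResults(
            c=c,
            phi=phi,
            theta=theta,
            omega=omega,
            alpha=alpha,
            beta=beta,
            sigma_t=sigma_t,
            std_resid=std_resid,
            resid=eps,
            loglik=float(loglik),
            converged=converged and not fallback,
            fallback_constant_variance=fallback,
            nobs=x.size,
        )


def fit_arma_garch(x, min_nobs: int = 50) -> ArmaGarchResults:
    """Functional wrapper: ``ArmaGarchModel(x).fit()``."""
    return ArmaGarchModel(x, min_nobs=min_nobs).fit()


# ---------------------------------------------------------------------------
# DCC(1,1) / EWMA time-varying correlation
# ---------------------------------------------------------------------------


def _dcc_path(eps: np.ndarray, a: float, b: float, qbar: np.ndarray) -> np.ndarray:
    """R_t path from the bivariate DCC recursion, Q_0 = Qbar."""
    T = eps.shape[0]
    q11, q12, q22 = qbar[0, 0], qbar[0, 1], qbar[1, 1]
    c11, c12, c22 = (1 - a - b) * q11, (1 - a - b) * q12, (1 - a - b) * q22
    p11, p12, p22 = q11, q12, q22
    r = np.empty(T)
    e1 = eps[:, 0]
    e2 = eps[:, 1]
    for t in range(T):
        r[t] = p12 / math.sqrt(p11 * p22)
        x1, x2 = e1[t], e2[t]
        p11 = c11 + a * x1 * x1 + b * p11
        p12 = c12 + a * x1 * x2 + b * p12
        p22 = c22 + a * x2 * x2 + b * p22
    return np.clip(r, -1.0, 1.0)


def _dcc_negll(eps: np.ndarray, a: float, b: float, qbar: np.ndarray) -> float:
    """Second-stage correlation quasi-likelihood (bivariate, explicit)."""
    T = eps.shape[0]
    q11, q12, q22 = qbar[0, 0], qbar[0, 1], qbar[1, 1]
    c11, c12, c22 = (1 - a - b) * q11, (1 - a - b) * q12, (1 - a - b) * q22
    p11, p12, p22 = q11, q12, q22
    e1 = eps[:, 0]
    e2 = eps[:, 1]
    nll = 0.0
    for t in range(T):
        r = p12 / math.sqrt(p11 * p22)
        r = max(min(r, 0.9999), -0.9999)
        det = 1.0 - r * r
        x1, x2 = e1[t], e2[t]
        nll += 0.5 * (
            math.log(det) + (x1 * x1 - 2.0 * r * x1 * x2 + x2 * x2) / det - (x1 * x1 + x2 * x2)
        )
        p11 = c11 + a * x1 * x1 + b * p11
        p12 = c12 + a * x1 * x2 + b * p12
        p22 = c22 + a * x2 * x2 + b * p22
    return nll


@dataclass
class DCCResults:
    """Time-varying correlation fit for one ROI pair."""

    a: float
    b: float
    lam: float | None
    qbar: np.ndarray
    R_t: np.ndarray
    mode: str
    loglik: float | None
    converged: bool
    boundary: bool = False

    @property
    def strength(self) -> float:
        """dFC strength: time mean of R_t."""
        return float(self.R_t.mean())

    @property
    def variability(self) -> float:
        """dFC variability: sample SD of R_t over time."""
        return float(self.R_t.std(ddof=1)) if self.R_t.size > 1 else 0.0

    def summary(self) -> str:
        lines = [
            f"DCC fit (mode={self.mode})",
            f"  nobs         {self.R_t.size}",
            (
                f"  a={self.a:.4f}  b={self.b:.4f}  a+b={self.a + self.b:.4f}"
                if self.mode == "dcc"
                else f"  lambda={self.lam:.4f}"
            ),
            f"  Qbar r       {self.qbar[0, 1]:+.4f}",
            f"  strength     {self.strength:+.4f}",
            f"  variability  {self.variability:.4f}",
            f"  converged    {self.converged}" + ("  [boundary]" if self.boundary else ""),
        ]
        return "\n".join(lines)


class DCCModel:
    """Bivariate DCC(1,1) on a pair of standardised-residual series.

    Qbar is the sample correlation matrix of the residuals (correlation
    targeting); (a, b) are estimated by second-stage quasi-MLE with the
    stationarity constraint a + b < 1 enforced by reparameterisation and
    three starting points.  mode="ewma" instead runs the fixed-decay
    exponentially weighted recursion Q_t = (1-lam) e_{t-1} e_{t-1}' + lam
    Q_{t-1} with no estimation.
    """

    def __init__(self, eps1, eps2, mode: str = "dcc", lam: float = 0.94):
        eps1 = np.asarray(eps1, dtype=float).ravel()
        eps2 = np.asarray(eps2, dtype=float).ravel()
        if eps1.shape != eps2.shape:
            raise ValueError("residual series must have equal length")
        if mode not in ("dcc", "ewma"):
            raise ValueError(f"unknown mode {mode!r}")
        if not (0.0 < lam < 1.0):
            raise ValueError("lambda must be in (0, 1)")
        self.eps = np.column_stack([eps1, eps2])
        self.mode = mode
        self.lam = lam

    def _qbar(self) -> np.ndarray:
        r = np.corrcoef(self.eps[:, 0], self.eps[:, 1])[0, 1]
        return np.array([[1.0, r], [r, 1.0]])

    def _ewma_path(self) -> np.ndarray:
        lam = self.lam
        qbar = self._qbar()
        T = self.eps.shape[0]
        p11, p12, p22 = qbar[0, 0], qbar[0, 1], qbar[1, 1]
        r = np.empty(T)
        for t in range(T):
            r[t] = p12 / math.sqrt(max(p11 * p22, 1e-300))
            x1, x2 = self.eps[t]
            p11 = (1 - lam) * x1 * x1 + lam * p11
            p12 = (1 - lam) * x1 * x2 + lam * p12
            p22 = (1 - lam) * x2 * x2 + lam * p22
        return np.clip(r, -1.0, 1.0)

    def fit(self, a: float | None = None, b: float | None = None) -> DCCResults:
        """Estimate (a, b) by quasi-MLE, or evaluate at forced values."""
        qbar = self._qbar()
        rho = qbar[0, 1]
        if self.mode == "ewma":
            return DCCResults(
                a=0.0, b=0.0, lam=self.lam, qbar=qbar, R_t=self._ewma_path(),
                mode="ewma", loglik=None, converged=True,
            )
        if abs(rho) >= 1.0 - 1e-10:
            # degenerate pair (e.g. identical series): correlation is pinned
            R = _dcc_path(self.eps, 0.0, 0.0, qbar)
            return DCCResults(
                a=0.0, b=0.0, lam=None, qbar=qbar, R_t=R, mode="dcc",
                loglik=None, converged=True, boundary=True,
            )
        if a is not None and b is not None:
            if a < 0 or b < 0 or a + b >= 1:
                raise ValueError("need a >= 0, b >= 0, a + b < 1")
            R = _dcc_path(self.eps, a, b, qbar)
            return DCCResults(
                a=a, b=b, lam=None, qbar=qbar, R_t=R, mode="dcc",
                loglik=-_dcc_negll(self.eps, a, b, qbar), converged=True,
            )

        def unpack(p):
            p = np.clip(p, -35.0, 35.0)
            ab = 0.999 / (1.0 + math.exp(-p[0]))
            frac = 1.0 / (1.0 + math.exp(-p[1]))
            return ab * frac, ab * (1.0 - frac)

        best = None
        for a0, b0 in [(0.05, 0.90), (0.02, 0.70), (0.10, 0.40)]:
            s0 = a0 + b0
            p0 = np.array([math.log(s0 / (0.999 - s0)), math.log(a0 / b0)])
            res = optimize.minimize(
                lambda p: _dcc_negll(self.eps, *unpack(p), qbar),
                p0,
                method="Nelder-Mead",
                options={"maxiter": 400, "xatol": 1e-5, "fatol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        a_hat, b_hat = unpack(best.x)
        boundary = a_hat + b_hat > 0.995
        if boundary:
            logger.warning("DCC optimizer near the a+b<1 boundary (a+b=%.4f)", a_hat + b_hat)
        R = _dcc_path(self.eps, a_hat, b_hat, qbar)
        return DCCResults(
            a=float(a_hat), b=float(b_hat), lam=None, qbar=qbar, R_t=R, mode="dcc",
            loglik=float(-best.fun), converged=bool(best.success), boundary=boundary,
        )


def fit_dcc(eps1, eps2, mode: str = "dcc", lam: float = 0.94, a=None, b=None) -> DCCResults:
    """Functional wrapper: ``DCCModel(eps1, eps2, mode).fit()``."""
    return DCCModel(eps1, eps2, mode=mode, lam=lam).fit(a=a, b=b)


def dfc_summaries(R_t) -> tuple[float, float]:
    """dFC strength and variability: mean and sample SD of the R_t path."""
    R_t = np.asarray(R_t, dtype=float).ravel()
    if R_t.size == 0:
        raise ValueError("empty correlation path")
    sd = float(R_t.std(ddof=1)) if R_t.size > 1 else 0.0
    return float(R_t.mean()), sd


def compare_dfc(values_a, values_b) -> tuple[float, float]:
    """Pooled-variance unpaired two-sample t test on per-subject summaries.

    Returns (t, two-tailed p); group A first, so a negative t means group A
    below group B.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance")
    return float(t), float(p)
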