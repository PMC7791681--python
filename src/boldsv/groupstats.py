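"""Voxel-wise group inference on z maps.

Covariate-adjusted GLM t-contrast on the group indicator, with family-wise
error control by permutation: either a cluster-extent test (uncorrected
height threshold + max-cluster-extent null) or threshold-free cluster
enhancement (TFCE) with a max-statistic null.  Covariates (age, sex, mean
framewise displacement) are handled by Freedman-Lane residual permutation;
for tiny designs without covariates the group-label space is enumerated
exhaustively instead of sampled.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .volume import grid_centers_mm

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDesign",
    "StatResult",
    "glm_ttest",
    "cluster_extent_fwe",
    "tfce_transform",
    "tfce_permutation",
    "make_sphere_mask",
]

#: 26-neighbour connectivity structure for 3D cluster labeling.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GroupDesign:
    """Per-subject z maps with a two-level group indicator and covariates.

    Parameters
    ----------
    z_maps : ndarray, (n_subjects, X, Y, Z)
        Subject-level z maps on a common grid.
    group : ndarray, (n_subjects,)
        Binary group indicator (0/1); the t contrast is on this column.
    covariates : ndarray, (n_subjects, k), optional
        Nuisance covariates (age, sex 0/1, mean FD).  Coding of sex does not
        affect the group-contrast t.
    mask : ndarray, (X, Y, Z) bool
        Analysis mask.
    affine : ndarray (4, 4), optional
        Used only to report cluster peaks in world mm.
    """

    z_maps: np.ndarray
    group: np.ndarray
    mask: np.ndarray
    covariates: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.z_maps = np.asarray(self.z_maps, dtype=float)
        self.group = np.asarray(self.group, dtype=float).ravel()
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z_maps.ndim != 4:
            raise ValueError("z_maps must be (n_subjects, X, Y, Z)")
        if self.z_maps.shape[0] != self.group.size:
            raise ValueError("z_maps and group length mismatch")
        levels = np.unique(self.group)
        if levels.size != 2:
            raise ValueError(f"group must have exactly two levels, got {levels}")
        for lev in levels:
            if (self.group == lev).sum() < 2:
                raise ValueError("need at least 2 subjects per group")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.group.size:
                raise ValueError("covariates rows must match n_subjects")

    @property
    def n_subjects(self) -> int:
        return self.group.size

    def design_matrix(self) -> np.ndarray:
        cols = [np.ones(self.n_subjects), self.group]
        if self.covariates is not None:
            cols.extend(self.covariates.T)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "rank-deficient design: a covariate is collinear with the "
                "intercept or group indicator"
            )
        return X

    def masked_data(self) -> np.ndarray:
        """(n_subjects, n_in_mask_voxels) data matrix; non-finite voxels dropped."""
        Y = self.z_maps[:, self.mask]
        bad = ~np.all(np.isfinite(Y), axis=0)
        if bad.any():
            logger.warning("excluding %d non-finite voxels from the analysis", int(bad.sum()))
            Y = np.where(bad[None, :], 0.0, Y)
        return Y


@dataclass
class StatResult:
    """Group-inference products: t map, clusters with FWE p, TFCE maps."""

    t_map: np.ndarray
    df: int
    height_p: float | None = None
    clusters: list[dict] = field(default_factory=list)
    tfce_map: np.ndarray | None = None
    fwe_p_map: np.ndarray | None = None
    n_permutations: int = 0
    seed: int | None = None
    perm_mode: str = "none"

    def significant_clusters(self, alpha: float = 0.05) -> list[dict]:
        return [c for c in self.clusters if c["p_fwe"] <= alpha]


def _t_contrast(X: np.ndarray, Y: np.ndarray, col: int = 1) -> tuple[np.ndarray, int]:
    """OLS t statistic for one design column at every voxel.

    Y is (n, V).  Returns (t (V,), df).
    """
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    cvar = np.linalg.inv(X.T @ X)[col, col]
    denom = np.sqrt(sigma2 * cvar)
    # voxels whose residual variance is zero up to round-off (perfect fit /
    # label-invariant data) get t = 0 rather than an fp-noise ratio
    degenerate = sigma2 <= (Y**2).mean(axis=0) * 1e-24
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~degenerate, beta[col] / np.where(denom > 0, denom, 1.0), 0.0)
    return t, df


def glm_ttest(design: GroupDesign) -> tuple[np.ndarray, int]:
    """Voxel-wise covariate-adjusted two-sample t map.

    Fits z ~ intercept + group + covariates by OLS per voxel; the t statistic
    is on the group coefficient.  With no covariates this equals the
    classical pooled two-sample t at every voxel.

    Returns
    -------
    (t_map, df) : 3D map (0 outside mask) and residual degrees of freedom.
    """
    X = design.design_matrix()
    Y = design.masked_data()
    t, df = _t_contrast(X, Y)
    t_map = np.zeros(design.mask.shape)
    t_map[design.mask] = t
    return t_map, df


def _label_clusters(supra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """26-connected components of a boolean 3D map -> (labels, sizes)."""
    labels, n = ndimage.label(supra, structure=CONNECTIVITY_26)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    sizes[0] = 0
    return labels, sizes


def _freedman_lane_perm_data(X: np.ndarray, Y: np.ndarray):
    """Reduced-model fit for Freedman-Lane permutation of the group effect."""
    Z = np.delete(X, 1, axis=1)  # covariates + intercept only
    qz, _ = np.linalg.qr(Z)
    fitted = qz @ (qz.T @ Y)
    resid = Y - fitted
    return fitted, resid


def cluster_extent_fwe(
    design: GroupDesign,
    height_p: float = 0.001,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    two_tailed: bool = True,
) -> StatResult:
    """Cluster-extent FWE correction by max-cluster-size permutation.

    Supra-threshold voxels (|t| above the two-tailed critical value at
    ``height_p``) are grouped into 26-connected clusters; the null
    distribution of the maximum cluster extent is built by Freedman-Lane
    permutation (residualise on covariates, permute residual rows, refit).
    Corrected p uses the add-the-observed convention, so p >= 1/(n_perm+1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    X = design.design_matrix()
    Y = design.masked_data()
    t, df = _t_contrast(X, Y)
    tcrit = stats.t.ppf(1 - height_p / 2, df) if two_tailed else stats.t.ppf(1 - height_p, df)

    t_map = np.zeros(design.mask.shape)
    t_map[design.mask] = t
    stat_map = np.abs(t_map) if two_tailed else t_map
    supra = (stat_map > tcrit) & design.mask
    labels, sizes = _label_clusters(supra)

    rng = np.random.default_rng(seed)
    fitted, resid = _freedman_lane_perm_data(X, Y)
    n = design.n_subjects
    max_sizes = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        t_p, _ = _t_contrast(X, fitted + resid[perm])
        sm = np.zeros(design.mask.shape)
        sm[design.mask] = np.abs(t_p) if two_tailed else t_p
        _, s = _label_clusters((sm > tcrit) & design.mask)
        max_sizes[i] = s.max() if s.size else 0

    clusters = []
    centers = grid_centers_mm(design.mask.shape, design.affine)
    for lab in range(1, sizes.size):
        voxels = np.argwhere(labels == lab)
        if voxels.size == 0:
            continue
        extent = int(sizes[lab])
        in_cluster = labels == lab
        peak_flat = np.argmax(np.where(in_cluster, stat_map, -np.inf))
        peak_ijk = np.unravel_index(peak_flat, labels.shape)
        p_fwe = (1 + int((max_sizes >= extent).sum())) / (n_perm + 1)
        clusters.append(
            {
                "extent": extent,
                "peak_ijk": tuple(int(v) for v in peak_ijk),
                "peak_mm": tuple(float(v) for v in centers[peak_ijk]),
                "peak_t": float(t_map[peak_ijk]),
                "p_fwe": float(p_fwe),
                "voxels": [tuple(int(v) for v in vx) for vx in voxels],
            }
        )
    clusters.sort(key=lambda c: -c["extent"])
    return StatResult(
        t_map=t_map,
        df=df,
        height_p=height_p,
        clusters=clusters,
        n_permutations=n_perm,
        seed=seed,
        perm_mode="freedman-lane",
    )


def tfce_transform(
    stat_map: np.ndarray,
    mask: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed statistic map.

    TFCE(v) = sum over thresholds h (from dh to the tail maximum in steps of
    dh) of e(h, v)^E * h^H * dh, where e(h, v) is the 26-connected extent of
    the supra-h component containing v.  The positive and negative tails are
    enhanced separately; the result carries the sign of the input.  If ``dh``
    is None it defaults to max|stat| / n_steps.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    stat_map = np.where(mask, stat_map, 0.0)
    vmax = np.abs(stat_map).max()
    if vmax == 0:
        return np.zeros_like(stat_map, dtype=float)
    if dh is None:
        dh = vmax / n_steps
    if not dh > 0:
        raise ValueError("dh must be positive")
    out = np.zeros_like(stat_map, dtype=float)
    for sign in (1.0, -1.0):
        tail = sign * stat_map
        tmax = tail.max(initial=0.0, where=mask)
        if tmax < dh:
            continue
        n_thr = int(math.floor(tmax / dh + 1e-12))
        for i in range(1, n_thr + 1):
            h = i * dh
            supra = (tail >= h) & mask
            if not supra.any():
                break
            labels, sizes = _label_clusters(supra)
            out[supra] += sign * sizes[labels[supra]] ** E * h**H * dh
    return out


def _n_label_arrangements(group: np.ndarray) -> int:
    n = group.size
    n1 = int((group == group.max()).sum())
    return math.comb(n, n1)


def tfce_permutation(
    design: GroupDesign,
    n_perm: int = 5000,
    seed: int | None = None,
    two_tailed: bool = True,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> StatResult:
    """Voxel-wise FWE-corrected p map via max-TFCE permutation.

    For each permutation the t map is recomputed (Freedman-Lane for sampled
    permutations; exhaustive group-label enumeration when the label space is
    no larger than ``n_perm`` and no covariates are present), TFCE-enhanced,
    and the mask-wide maximum |TFCE| recorded.  FWE p(v) = (1 + #{perm max >=
    |TFCE_obs(v)|}) / (n_used + 1).
    """
    X = design.design_matrix()
    Y = design.masked_data()
    t, df = _t_contrast(X, Y)
    t_map = np.zeros(design.mask.shape)
    t_map[design.mask] = t
    obs_tfce = tfce_transform(t_map if two_tailed else np.maximum(t_map, 0), design.mask, E, H, dh, n_steps)
    obs_abs = np.abs(obs_tfce) if two_tailed else obs_tfce

    n = design.n_subjects
    n_arrangements = _n_label_arrangements(design.group)
    exhaustive = design.covariates is None and n_arrangements <= n_perm

    def perm_stat(Yp: np.ndarray, Xp: np.ndarray) -> float:
        t_p, _ = _t_contrast(Xp, Yp)
        sm = np.zeros(design.mask.shape)
        sm[design.mask] = t_p
        tf = tfce_transform(sm if two_tailed else np.maximum(sm, 0), design.mask, E, H, dh, n_steps)
        return float(np.abs(tf).max() if two_tailed else tf.max())

    if exhaustive:
        logger.info("enumerating all %d group-label arrangements exhaustively", n_arrangements)
        n1 = int((design.group == design.group.max()).sum())
        null_max = []
        for idx in itertools.combinations(range(n), n1):
            g = np.zeros(n)
            g[list(idx)] = 1.0
            Xp = X.copy()
            Xp[:, 1] = g
            null_max.append(perm_stat(Y, Xp))
        null_max = np.asarray(null_max)
        n_used = null_max.size
        mode = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        fitted, resid = _freedman_lane_perm_data(X, Y)
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            null_max[i] = perm_stat(fitted + resid[rng.permutation(n)], X)
        n_used = n_perm
        mode = "freedman-lane"

    null_sorted = np.sort(null_max)
    vals = obs_abs[design.mask]
    # number of null maxima >= observed value, per voxel
    ge = n_used - np.searchsorted(null_sorted, vals, side="left")
    p = (1.0 + ge) / (n_used + 1.0)
    p_map = np.ones(design.mask.shape)
    p_map[design.mask] = p
    return StatResult(
        t_map=t_map,
        df=df,
        tfce_map=obs_tfce,
        fwe_p_map=p_map,
        n_permutations=n_used,
        seed=seed,
        perm_mode=mode,
    )


def make_sphere_mask(
    centers_mm,
    grid_shape,
    affine,
    radius_mm: float = 5.0,
) -> np.ndarray:
    """Union of spheres as a boolean mask on the given grid.

    Membership is by voxel-center Euclidean distance in world mm, inclusive
    boundary (<= radius).  On a 2-mm isotropic grid a 5-mm sphere centered on
    a voxel center contains 81 voxels.
    """
    centers = grid_centers_mm(grid_shape, affine)
    mask = np.zeros(grid_shape, dtype=bool)
    for c in np.atleast_2d(np.asarray(centers_mm, dtype=float)):
        mask |= np.linalg.norm(centers - c, axis=-1) <= radius_mm
    if not mask.any():
        raise ValueError("sphere mask is empty: centers lie outside the grid")
    return mask
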