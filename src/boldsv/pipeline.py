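"""End-to-end pipeline driver over a synthetic (or pre-loaded) cohort.

Stages: cohort ingest -> preprocessing (volume discard, grand-mean scaling,
nuisance + trend regression, smoothing, band-pass) -> variability maps in
four bands -> group inference (cluster-extent FWE on the whole mask, TFCE on
a small sphere mask) -> ROI dynamic connectivity -> clinical correlation.
Writes a JSON manifest with parameters, seeds and per-stage content hashes;
identical configs reproduce identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import correlate_family
from .connectivity import DCCModel, ArmaGarchModel, RoiSpec, extract_roi_series
from .groupstats import (
    GroupDesign,
    cluster_extent_fwe,
    make_sphere_mask,
    tfce_permutation,
)
from .preprocess import (
    DEFAULT_BANDS,
    bandpass,
    discard_initial_volumes,
    framewise_displacement,
    grand_mean_scale,
    regress_nuisance,
    smooth_gaussian,
)
from .synthetic import EffectBlob, SyntheticCohortConfig, simulate_cohort, simulate_clinical_table
from .variability import compute_sv, standardize_sv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "default_smoke_config"]


@dataclass
class PipelineConfig:
    """Declarative configuration for one full run."""

    cohort: SyntheticCohortConfig
    out_dir: str = "boldsv_out"
    k_discard: int = 5
    fwhm_mm: float = 6.0
    height_p: float = 0.001
    cluster_alpha: float = 0.05
    n_perm_cluster: int = 300
    n_perm_tfce: int = 500
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_n_steps: int = 50
    roi_radius_mm: float = 5.0
    seed: int = 0
    q_level: float = 0.05
    n_roi_pairs: int = 2

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["cohort"]["effect_blobs"] = [asdict(b) for b in self.cohort.effect_blobs]
        return d


def default_smoke_config(out_dir: str = "boldsv_out", seed: int = 0) -> PipelineConfig:
    """Small bundled configuration: 8 vs 8 subjects, 20^3 grid, T = 120."""
    blob = EffectBlob(center_vox=(6, 6, 10), radius_mm=5.0, multiplier=1.6)
    cohort = SyntheticCohortConfig(
        n_group_a=8,
        n_group_b=8,
        grid_shape=(20, 20, 20),
        n_volumes=120,
        effect_blobs=[blob],
        seed=seed,
    )
    return PipelineConfig(cohort=cohort, out_dir=out_dir, seed=seed)


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False, float_format="%.12g").encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return (and write) the output manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_jsonable(),
        "stages": {},
    }

    cohort = simulate_cohort(config.cohort)
    manifest["stages"]["simulate"] = {
        "n_subjects": len(cohort.subjects),
        "effect_mask_hash": _hash_array(cohort.effect_mask.astype(np.uint8)),
    }

    bands = DEFAULT_BANDS
    mask = cohort.gm_mask
    z_maps: dict[str, list[np.ndarray]] = {name: [] for name in bands}
    mean_fds = []
    preproc_vols = []
    for subj in cohort.subjects:
        try:
            vol = discard_initial_volumes(subj.volume, config.k_discard)
            motion = subj.motion.to_numpy()[config.k_discard :]
            nuisance = np.column_stack([subj.nuisance.to_numpy()[config.k_discard :], motion])
            vol = grand_mean_scale(vol)
            vol = regress_nuisance(vol, nuisance, detrend=True)
            vol = smooth_gaussian(vol, config.fwhm_mm)
            _, mean_fd = framewise_displacement(motion)
            mean_fds.append(mean_fd)
            filt = bandpass(vol, bands["overall"])
            preproc_vols.append(filt)
            for name, band in bands.items():
                bvol = filt if name == "overall" else bandpass(vol, band)
                z_maps[name].append(standardize_sv(compute_sv(bvol, mask), mask))
        except Exception as exc:  # noqa: BLE001 - stage failures must name the subject
            raise RuntimeError(f"preprocess failed for subject {subj.subject_id}: {exc}") from exc
    manifest["stages"]["preprocess"] = {
        "mean_fd": [round(v, 6) for v in mean_fds],
        "z_map_hashes": {
            name: _hash_array(np.stack(maps)) for name, maps in z_maps.items()
        },
    }

    rng = np.random.default_rng(config.seed)
    group = np.array([0.0 if g == "A" else 1.0 for g in cohort.groups])
    n = group.size
    covariates = np.column_stack(
        [
            np.clip(rng.normal(28.5, 7.0, n), 18, 45),  # age
            rng.integers(0, 2, n).astype(float),  # sex
            np.asarray(mean_fds),
        ]
    )
    design = GroupDesign(
        z_maps=np.stack(z_maps["overall"]),
        group=group,
        covariates=covariates,
        mask=mask,
        affine=cohort.config.affine,
    )
    stat = cluster_extent_fwe(
        design,
        height_p=config.height_p,
        n_perm=config.n_perm_cluster,
        alpha=config.cluster_alpha,
        seed=config.seed,
    )
    sig = stat.significant_clusters(config.cluster_alpha)
    cluster_rows = [
        {k: c[k] for k in ("extent", "peak_mm", "peak_t", "p_fwe")} for c in stat.clusters
    ]
    manifest["stages"]["groupstats_cluster"] = {
        "df": stat.df,
        "n_permutations": stat.n_permutations,
        "perm_mode": stat.perm_mode,
        "n_clusters": len(stat.clusters),
        "n_significant": len(sig),
        "clusters": cluster_rows[:20],
        "t_map_hash": _hash_array(stat.t_map),
    }

    # TFCE on a small sphere mask at the first planted blob (SpV-mask analog)
    if cohort.config.effect_blobs:
        blob = cohort.config.effect_blobs[0]
        centers = design.affine @ np.array([*blob.center_vox, 1.0])
        sphere = make_sphere_mask(
            [centers[:3]], cohort.config.grid_shape, design.affine, radius_mm=5.0
        )
        tfce_design = GroupDesign(
            z_maps=design.z_maps,
            group=group,
            covariates=covariates,
            mask=sphere,
            affine=design.affine,
        )
        tfce_res = tfce_permutation(
            tfce_design,
            n_perm=config.n_perm_tfce,
            seed=config.seed,
            E=config.tfce_E,
            H=config.tfce_H,
            n_steps=config.tfce_n_steps,
        )
        manifest["stages"]["groupstats_tfce"] = {
            "n_permutations": tfce_res.n_permutations,
            "perm_mode": tfce_res.perm_mode,
            "min_fwe_p": float(tfce_res.fwe_p_map[sphere].min()),
            "fwe_p_hash": _hash_array(tfce_res.fwe_p_map),
        }

    # dynamic connectivity on ROI pairs centred on/off the first blob
    blob_world = (
        design.affine @ np.array([*cohort.config.effect_blobs[0].center_vox, 1.0])
    )[:3] if cohort.config.effect_blobs else np.zeros(3)
    offsets = [np.zeros(3), np.array([10.0, 0, 0]), np.array([0, 10.0, 0]), np.array([0, 0, 10.0])]
    rois = [
        RoiSpec(f"roi{i}", tuple(blob_world + off), config.roi_radius_mm)
        for i, off in enumerate(offsets)
    ]
    pairs = [(rois[0], rois[1]), (rois[2], rois[3])][: config.n_roi_pairs]
    dfc_rows = []
    for subj, vol in zip(cohort.subjects, preproc_vols):
        try:
            series = {r.name: extract_roi_series(vol, r, band=None) for r in rois}
            for ra, rb in pairs:
                fa = ArmaGarchModel(series[ra.name]).fit()
                fb = ArmaGarchModel(series[rb.name]).fit()
                dcc = DCCModel(fa.std_resid, fb.std_resid).fit()
                dfc_rows.append(
                    {
                        "subject": subj.subject_id,
                        "group": subj.group,
                        "pair": f"{ra.name}-{rb.name}",
                        "strength": dcc.strength,
                        "variability": dcc.variability,
                        "a": dcc.a,
                        "b": dcc.b,
                        "converged": bool(fa.converged and fb.converged and dcc.converged),
                    }
                )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"connectivity failed for subject {subj.subject_id}: {exc}") from exc
    dfc = pd.DataFrame(dfc_rows)
    dfc.to_csv(out / "dfc_summaries.csv", index=False)
    group_tests = []
    from .connectivity import compare_dfc

    for pair_name, sub in dfc.groupby("pair"):
        for measure in ("strength", "variability"):
            va = sub.loc[sub["group"] == "A", measure]
            vb = sub.loc[sub["group"] == "B", measure]
            t, p = compare_dfc(va, vb)
            group_tests.append({"pair": pair_name, "measure": measure, "t": t, "p": p})
    manifest["stages"]["connectivity"] = {
        "n_pairs": len(pairs),
        "n_converged": int(dfc["converged"].sum()),
        "n_fits": len(dfc),
        "group_tests": group_tests,
        "dfc_hash": _hash_df(dfc),
    }

    # clinical: rank-correlate a patient covariate against planted pain scores
    n_b = cohort.config.n_group_b
    clin = simulate_clinical_table(n=max(n_b, 3), seed=config.seed, rho_target=0.6)
    corr = correlate_family(
        {"covariate-vs-pains": (clin["covariate"].to_numpy(), clin["pains_pct"].to_numpy())},
        q_level=config.q_level,
    )
    clin.to_csv(out / "clinical.csv", index=False)
    manifest["stages"]["clinical"] = {
        "correlations": corr.to_dict(orient="records"),
        "table_hash": _hash_df(clin),
    }

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
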