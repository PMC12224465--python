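"""End-to-end orchestration: simulate -> preprocess -> denoise -> topography
-> group GLM -> QC.

Each stage writes its outputs under the run directory and later stages read
those serialized artifacts; a provenance JSON records the config, per-stage
seeds, and input hashes, so re-running with an identical config reproduces
deterministic stages bit-for-bit.

Output layout::

    <out>/cohort/                 subject NIfTIs, motion text, participants.tsv
    <out>/<pipeline>/<subject>/   preprocessed run + topography maps
    <out>/group/<model>/<contrast>/  group z maps + cluster tables
    <out>/qc/                     phenotype checks, pipeline correlations, PLS
    <out>/provenance.json
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as gio
from .config import RunConfig, stage_int_seed
from .cohort import simulate_cohort
from .exceptions import ProvenanceError
from .glm import build_design, grf_cluster_correct, voxelwise_glm
from .ica import run_cascade
from .preprocess import (bandpass, friston24, gaussian_smooth, make_censor_mask,
                         regress_nuisance, tissue_mean_series, NuisanceSet)
from .qc import (block_parcellation, distance_dependence, parcel_fc,
                 phenotype_age_checks, pipeline_correlations, pls_fd)
from .topography import compute_gs, gray_mask, topography_map

__all__ = ["run_pipeline", "preprocess_run"]


def preprocess_run(run, pipeline: str, atlas, censor=None):
    """Apply one named preprocessing chain (mp or cr) to a single run."""
    from .config import PreprocessConfig
    cfg = PreprocessConfig()
    out = gaussian_smooth(run, cfg.smooth_fwhm)
    if pipeline == "cr":
        tissue_labels = atlas.region_table
        wm = tissue_labels.loc[tissue_labels.tissue == "white", "label"].to_numpy()
        csf = tissue_labels.loc[tissue_labels.tissue == "csf", "label"].to_numpy()
        # tissue series come from the unsmoothed run: smoothing at this grid
        # scale bleeds gray-matter signal into the small WM/CSF cores
        nuis = friston24(out.motion_params).stacked_with(NuisanceSet(
            np.column_stack([tissue_mean_series(run, atlas.labels, wm),
                             tissue_mean_series(run, atlas.labels, csf)]),
            ["wm_mean", "csf_mean"], detrend_flag=True))
        out = regress_nuisance(out, nuis, censor)
    return bandpass(out, 0.01, 0.1)


def run_pipeline(config: RunConfig, out_dir, stages: tuple[str, ...] | None = None) -> dict:
    """Run the configured stages; returns a dict of key results and paths."""
    all_stages = ("simulate", "preprocess", "topography", "glm", "qc")
    stages = tuple(stages) if stages else all_stages
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"config": config.model_dump(mode="json"), "stages": {}}
    results: dict = {}

    # ------------------------------------------------------------------ simulate
    cohort_dir = out / "cohort"
    if "simulate" in stages:
        phenos, atlas, runs, latents = simulate_cohort(
            config.cohort.n_subjects, config.seed,
            grid_shape=config.grid.shape,
            t_frames=config.bold.t_frames,
            cohort_config=config.cohort, bold_config=config.bold)
        manifest = gio.write_cohort(runs, phenos, cohort_dir, atlas=atlas,
                                    params={"seed": config.seed})
        provenance["stages"]["simulate"] = {"seed": config.seed,
                                            "files": manifest["files"]}
    else:
        if not (cohort_dir / "manifest.json").exists():
            raise ProvenanceError("stage 'simulate' output missing: run simulate first")
        runs, phenos, atlas, _ = gio.read_cohort(cohort_dir)
        latents = None

    gm = gray_mask(atlas.gm_probability, config.preprocess.gm_threshold)
    results["phenotypes"] = phenos
    results["atlas"] = atlas

    # ---------------------------------------------------------------- preprocess
    processed: dict[str, list] = {}
    if "preprocess" in stages:
        censors = [make_censor_mask(p.fd_trace, config.preprocess.fd_threshold,
                                    config.preprocess.min_retained)
                   if config.scrub else None for p in phenos]
        for pipe in config.pipelines:
            if pipe == "tica":
                smoothed = [gaussian_smooth(r, config.preprocess.smooth_fwhm)
                            for r in runs]
                model, cleaned = run_cascade(
                    smoothed, mask=atlas.labels > 0, gray=gm,
                    k_sica=config.ica.desk_k_sica, k_tica=config.ica.desk_k_tica,
                    seed=stage_int_seed(config.seed, "tica"),
                    labels="manifest" if latents is not None else "auto",
                    latents=latents)
                processed[pipe] = cleaned
                results["ica_model"] = model
                from .ica import save_cascade
                save_cascade(model, out / "tica_model",
                             voxel_size=config.grid.voxel_size)
            else:
                processed[pipe] = [preprocess_run(r, pipe, atlas, c)
                                   for r, c in zip(runs, censors)]
        results["censors"] = censors
        provenance["stages"]["preprocess"] = {"pipelines": list(config.pipelines),
                                              "scrub": config.scrub}
    else:
        censors = [None] * len(runs)

    # ---------------------------------------------------------------- topography
    maps: dict[str, list] = {}
    gs_series: dict[str, list] = {}
    if "topography" in stages:
        import pandas as pd
        for pipe, pruns in processed.items():
            maps[pipe], gs_series[pipe] = [], []
            for r, c in zip(pruns, censors):
                gs = compute_gs(r, gm, source_pipeline=pipe)
                gs_series[pipe].append(gs)
                tmap = topography_map(
                    r, gs, censor=c if config.scrub else None,
                    mask=atlas.labels > 0, z_dialect=config.glm.z_dialect)
                maps[pipe].append(tmap)
                sdir = out / pipe / r.phenotype_ref
                sdir.mkdir(parents=True, exist_ok=True)
                gio.save_nifti(tmap.beta.astype(np.float32),
                               sdir / "topography_beta.nii.gz",
                               config.grid.voxel_size)
                gio.save_nifti(tmap.z.astype(np.float32),
                               sdir / "topography_z.nii.gz",
                               config.grid.voxel_size)
                pd.DataFrame({"gs": gs.values}).to_csv(sdir / "gs.tsv",
                                                       sep="\t", index=False)
        results["maps"] = maps
        results["gs_series"] = gs_series
        provenance["stages"]["topography"] = {
            "mask_voxels": int(gm.sum()), "scrub": config.scrub}

    # ----------------------------------------------------------------------- glm
    if "glm" in stages and maps:
        glm_out = {}
        primary = "tica" if "tica" in maps else list(maps)[0]
        for model_name, quadratic in (("linear", False), ("quadratic", True)):
            design = build_design(phenos, quadratic=quadratic)
            contrast = "age_quadratic" if quadratic else "age_linear"
            res = voxelwise_glm(maps[primary], design, contrast,
                                voxel_size=config.grid.voxel_size)
            tables = {
                sign: grf_cluster_correct(res, config.glm.voxel_p,
                                          config.glm.cluster_p, sign=sign,
                                          connectivity=config.glm.connectivity)
                for sign in ("pos", "neg")}
            gdir = out / "group" / model_name / contrast
            gdir.mkdir(parents=True, exist_ok=True)
            gio.save_nifti(res.zstat.astype(np.float32), gdir / "zstat.nii.gz",
                           config.grid.voxel_size)
            for sign, tab in tables.items():
                tab.to_csv(gdir / f"clusters_{sign}.tsv", sep="\t", index=False)
            glm_out[model_name] = {"result": res, "clusters": tables}
        results["glm"] = glm_out
        provenance["stages"]["glm"] = {"pipeline": primary,
                                       "models": list(glm_out)}

    # ------------------------------------------------------------------------ qc
    if "qc" in stages and maps:
        qc_dir = out / "qc"
        qc_dir.mkdir(parents=True, exist_ok=True)
        checks = phenotype_age_checks(phenos, config.preprocess.fd_threshold)
        checks.to_csv(qc_dir / "phenotype_checks.tsv", sep="\t", index=False)

        primary = "tica" if "tica" in maps else list(maps)[0]
        parcels = block_parcellation(gm, config.qc.parcel_block)
        fcs, cents = [], None
        for r in processed[primary]:
            fc, cents = parcel_fc(r, parcels)
            fcs.append(fc)
        fd = np.array([p.mean_fd for p in phenos])
        profile = distance_dependence(np.stack(fcs), fd, cents)

        stacked = np.stack([np.nan_to_num(m.z[atlas.labels > 0]) for m in maps[primary]])
        pls = pls_fd(stacked, fd, n_perm=config.qc.n_perm, n_boot=config.qc.n_boot,
                     seed=stage_int_seed(config.seed, "pls"))

        import pandas as pd
        pd.DataFrame({"distance_mm": profile.distances,
                      "fd_fc_r": profile.fd_fc_correlation}).to_csv(
            qc_dir / "distance_profile.tsv", sep="\t", index=False)
        pd.DataFrame({"subject_id": [p.subject_id for p in phenos],
                      "brain_score": pls.brain_scores}).to_csv(
            qc_dir / "pls_brain_scores.tsv", sep="\t", index=False)

        corrs = {}
        if len(maps) > 1:
            corrs["gs_temporal"] = pipeline_correlations(
                {k: [g.values for g in v] for k, v in gs_series.items()},
                "gs_temporal")
            corrs["map_spatial"] = pipeline_correlations(
                {k: [m.z[atlas.labels > 0] for m in v] for k, v in maps.items()},
                "map_spatial")
            for model_name, quadratic in (("glm_linear", False),
                                          ("glm_quadratic", True)):
                contrast = "age_quadratic" if quadratic else "age_linear"
                design = build_design(phenos, quadratic=quadratic)
                group_z = {}
                for pipe, pmaps in maps.items():
                    r = voxelwise_glm(pmaps, design, contrast,
                                      voxel_size=config.grid.voxel_size,
                                      keep_residuals=False)
                    group_z[pipe] = [r.zstat[r.mask]]
                corrs[model_name] = pipeline_correlations(group_z, model_name)
            for lvl, m in corrs.items():
                pd.DataFrame(m.matrix, index=m.labels, columns=m.labels).to_csv(
                    qc_dir / f"pipeline_corr_{lvl}.tsv", sep="\t")
        results["qc"] = {"phenotype_checks": checks, "distance": profile,
                         "pls": pls, "pipeline_corrs": corrs}
        provenance["stages"]["qc"] = {"n_perm": config.qc.n_perm,
                                      "n_edges": len(profile.distances)}

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    results["provenance"] = provenance
    return results
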