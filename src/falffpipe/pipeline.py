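"""End-to-end orchestration: clean runs, map fALFF, fit the group model.

The per-subject chain follows the standard order: despike, joint
nuisance regression (trend + Friston-24 motion + aCompCor + global
signal), Gaussian smoothing; fALFF is computed on the smoothed
residuals, z-scored globally, and the z-maps are stacked into the
second-level interaction GLM with permutation cluster-FWE.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from falffpipe import glm as glm_mod
from falffpipe import nuisance as nz
from falffpipe.cohort import CohortTable
from falffpipe.config import BandConfig, GlmConfig, NuisanceConfig, PipelineConfig
from falffpipe.falff import BandDefinition, falff_map, zscore_map
from falffpipe.synth import BoldRun

log = logging.getLogger(__name__)


def clean_run(run: BoldRun, config: NuisanceConfig | None = None) -> tuple[np.ndarray, dict]:
    """Apply the full nuisance chain to one run.

    Returns the cleaned (smoothed residual) 4D array and a provenance
    dict recording the regressors kept and dropped.  Lesion voxels are
    removed from the white-matter and CSF masks before erosion, so
    aCompCor never draws components from damaged tissue.
    """
    config = config or NuisanceConfig()
    brain = run.brain_mask
    data = run.data.astype(float, copy=True)

    voxels = data[brain]
    if config.despike_enabled:
        voxels = nz.despike(voxels, clip_k=config.despike_clip_k)

    working = np.zeros_like(data)
    working[brain] = voxels

    wm = run.wm_mask & ~run.lesion_mask
    csf = run.csf_mask & ~run.lesion_mask
    wm_eroded = nz.erode_mask(wm, iterations=config.erode_iterations)
    csf_eroded = nz.erode_mask(csf, iterations=config.erode_iterations)

    wm_pcs = nz.acompcor(working, wm_eroded, n_components=config.acompcor_n_components)
    csf_pcs = nz.acompcor(working, csf_eroded, n_components=config.acompcor_n_components)
    gsig = nz.global_signal(working, brain) if config.gsr_enabled else None

    design = nz.build_nuisance_design(
        n_volumes=data.shape[-1],
        motion=run.motion,
        wm_components=wm_pcs,
        csf_components=csf_pcs,
        global_sig=gsig,
    )
    residual_voxels = nz.regress_nuisance(voxels, design)
    residuals = np.zeros_like(data)
    residuals[brain] = residual_voxels
    cleaned = nz.smooth(residuals, fwhm_mm=config.smooth_fwhm_mm, voxel_size_mm=run.voxel_size_mm)
    provenance = {
        "subject_id": run.subject_id,
        "n_regressors": design.n_regressors,
        "regressors": design.labels,
        "dropped": design.dropped,
        "despike": config.despike_enabled,
        "gsr": config.gsr_enabled,
        "smooth_fwhm_mm": config.smooth_fwhm_mm,
    }
    return cleaned, provenance


def band_definitions(bands: tuple[BandConfig, ...]) -> list[BandDefinition]:
    return [BandDefinition(b.name, b.lo_hz, b.hi_hz) for b in bands]


def subject_falff(
    run: BoldRun,
    bands: list[BandDefinition],
    nuisance_config: NuisanceConfig | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Clean one run and return its z-scored fALFF map per band."""
    cleaned, provenance = clean_run(run, nuisance_config)
    maps = {}
    for band in bands:
        fmap = falff_map(cleaned, run.brain_mask, run.tr_seconds, band)
        zscore_map(fmap)
        maps[band.name] = fmap.zscored
    return maps, provenance


def stack_maps(maps_per_subject: list[np.ndarray], mask: np.ndarray) -> np.ndarray:
    """Stack per-subject 3D maps into the n x V matrix the GLM consumes."""
    mask = np.asarray(mask, dtype=bool)
    return np.stack([m[mask] for m in maps_per_subject])


def analyze_band(
    cohort: CohortTable,
    maps_per_subject: list[np.ndarray],
    mask: np.ndarray,
    glm_config: GlmConfig | None = None,
    affine: np.ndarray | None = None,
    label_volume: np.ndarray | None = None,
) -> dict:
    """Second-level interaction analysis of one band.

    Returns t/z/r2 volumes, the raw cluster table, and the rendered
    report with mm coordinates.
    """
    glm_config = glm_config or GlmConfig()
    design = glm_mod.build_design(cohort, covariates=glm_config.covariates)
    stacked = stack_maps(maps_per_subject, mask)
    clusters = glm_mod.cluster_fwe(
        stacked,
        design,
        mask,
        p_form=glm_config.p_form,
        alpha=glm_config.alpha,
        n_perm=glm_config.n_perm,
        seed=glm_config.seed,
        connectivity=glm_config.connectivity,
        one_sided=glm_config.one_sided,
    )
    df = design.residual_df
    t_flat = glm_mod.fit_voxelwise(stacked, design)
    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t_flat
    z_vol = np.zeros(mask.shape)
    z_vol[mask] = glm_mod.t_to_z(t_flat, df)
    r2_vol = np.zeros(mask.shape)
    r2_vol[mask] = glm_mod.r_squared(t_flat, df)
    affine = affine if affine is not None else np.eye(4)
    report = glm_mod.report_clusters(clusters, affine, label_volume=label_volume)
    return {
        "design": design,
        "df": df,
        "t_map": t_vol,
        "z_map": z_vol,
        "r2_map": r2_vol,
        "clusters": clusters,
        "report": report,
    }


def run_falff_stage(config: PipelineConfig, runs: list[BoldRun] | None = None) -> dict[str, dict[str, np.ndarray]]:
    """Per-subject fALFF z-maps for every subject in the data directory.

    When ``runs`` is None, subjects are loaded from ``config.data_dir``
    (as written by the synthetic generator).  Maps and per-subject
    provenance JSON are written under ``config.output_dir``.
    """
    from falffpipe.cohort import load_cohort
    from falffpipe.synth import load_run

    data_dir = Path(config.data_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(data_dir / Path(config.cohort_csv).name)
    bands = band_definitions(config.bands)

    run_map = {r.subject_id: r for r in runs} if runs is not None else None
    all_maps: dict[str, dict[str, np.ndarray]] = {}
    for record in cohort:
        sid = record.subject_id
        run = run_map[sid] if run_map is not None else load_run(data_dir, sid)
        try:
            maps, provenance = subject_falff(run, bands, config.nuisance)
        except Exception as exc:
            raise RuntimeError(f"subject {sid}: fALFF stage failed ({exc})") from exc
        all_maps[sid] = maps
        vs = run.voxel_size_mm
        affine = np.diag([vs, vs, vs, 1.0])
        for band_name, volume in maps.items():
            img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
            img.to_filename(str(out_dir / f"{sid}_{band_name}_falff_z.nii"))
        with open(out_dir / f"{sid}_provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        log.info("subject %s: %d bands mapped (%d regressors)", sid, len(maps), provenance["n_regressors"])
    return all_maps


def run_analyze_stage(
    config: PipelineConfig,
    all_maps: dict[str, dict[str, np.ndarray]] | None = None,
) -> dict[str, dict]:
    """Second-level analysis per band; writes stat maps and cluster TSVs."""
    from falffpipe.cohort import load_cohort

    data_dir = Path(config.data_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(data_dir / Path(config.cohort_csv).name)
    brain = np.asarray(
        nib.load(str(data_dir / "masks" / "brain_mask.nii")).dataobj
    ).astype(bool)
    vs = config.synthetic.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    label_volume = None
    if config.label_volume:
        label_volume = np.asarray(nib.load(config.label_volume).dataobj).astype(int)
        if label_volume.shape != brain.shape:
            raise ValueError("label volume grid does not match the data grid")

    results = {}
    for band in band_definitions(config.bands):
        if all_maps is not None:
            maps = [all_maps[r.subject_id][band.name] for r in cohort]
        else:
            maps = []
            for record in cohort:
                path = out_dir / f"{record.subject_id}_{band.name}_falff_z.nii"
                if not path.exists():
                    raise FileNotFoundError(f"missing map for subject {record.subject_id}: {path}")
                maps.append(np.asarray(nib.load(str(path)).dataobj, dtype=float))
        result = analyze_band(
            cohort, maps, brain, config.glm, affine=affine, label_volume=label_volume
        )
        results[band.name] = result
        for kind in ("t_map", "z_map", "r2_map"):
            img = nib.Nifti1Image(np.asarray(result[kind], dtype=np.float32), affine)
            img.to_filename(str(out_dir / f"{band.name}_{kind.replace('_map', '')}.nii"))
        result["report"].to_csv(out_dir / f"{band.name}_clusters.tsv", sep="\t", index=False)
        run_info = {
            "band": band.name,
            "df": result["df"],
            "p_form": config.glm.p_form,
            "alpha": config.glm.alpha,
            "n_perm": config.glm.n_perm,
            "seed": config.glm.seed,
            "connectivity": config.glm.connectivity,
        }
        with open(out_dir / f"{band.name}_run_report.json", "w") as fh:
            json.dump(run_info, fh, indent=2, sort_keys=True)
    return results


def write_provenance(config: PipelineConfig, out_dir: str | Path) -> None:
    """Machine-readable record sufficient to reproduce a run."""
    from falffpipe import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"config": config.to_dict(), "version": __version__}
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
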