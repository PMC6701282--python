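"""Voxelwise group x score interaction GLM with cluster-extent FWE control.

The second-level model regresses each voxel's (z-scored) fALFF value on
``[intercept, group, score, group x score]`` (optionally mean-centred
age/sex/NIHSS covariates).  The statistic of interest is the t-value of
the interaction column: a positive interaction means the fALFF-score
slope is steeper in the high-symptom group.

Familywise error over clusters is controlled by permutation rather than
random-field theory: clusters are formed at a voxelwise threshold
(default p < 0.001, one-sided) and their extents compared against the
null distribution of the maximum cluster extent obtained by
Freedman-Lane permutation of reduced-model residuals — the standard
scheme for permuting one term of a multiple regression in the presence
of nuisance terms.  Corrected p-values use the (1+b)/(1+m) estimator and
are exact at any number of permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import ndtri_exp

from falffpipe.cohort import CohortTable

log = logging.getLogger(__name__)

CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

CLUSTER_COLUMNS = ["region", "x_mm", "y_mm", "z_mm", "k", "t", "z", "r2", "p_fwe"]


@dataclass
class DesignMatrix:
    """Second-level design: n x k matrix, labels, interaction contrast."""

    columns: np.ndarray
    labels: list[str]
    contrast: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.columns.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.columns))

    @property
    def residual_df(self) -> int:
        return self.n_subjects - self.columns.shape[1]


def build_design(cohort: CohortTable, covariates: tuple[str, ...] = ()) -> DesignMatrix:
    """Build the interaction design from a cohort table.

    Columns are ``[intercept, group, score, group x score]`` with the
    low-symptom group coded 0 and high coded 1; the score column is the
    raw MADRS total (not centred, so the interaction column carries the
    paper-style parameterisation).  Optional covariates from
    ``{"age", "sex", "nihss"}`` are appended mean-centred (sex coded
    female=0, male=1 before centring).  The contrast selects the
    interaction column.
    """
    frame = cohort.to_frame()
    if frame["group"].nunique() < 2:
        raise ValueError("cohort contains a single group; the interaction model needs both")
    group = (frame["group"] == "high").to_numpy(dtype=float)
    score = frame["madrs_total"].to_numpy(dtype=float)
    cols = [np.ones(len(frame)), group, score, group * score]
    labels = ["intercept", "group", "score", "group_x_score"]
    for cov in covariates:
        if cov == "sex":
            values = (frame["sex"] == "male").to_numpy(dtype=float)
        elif cov in ("age", "nihss"):
            values = frame[cov].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
        cols.append(values - values.mean())
        labels.append(cov)
    matrix = np.column_stack(cols)
    if np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        raise ValueError("rank-deficient design (e.g. constant score within the cohort)")
    contrast = np.zeros(matrix.shape[1])
    contrast[labels.index("group_x_score")] = 1.0
    return DesignMatrix(columns=matrix, labels=labels, contrast=contrast)


def fit_voxelwise(maps: np.ndarray, design: DesignMatrix, contrast: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel OLS t-map for a contrast.

    ``maps`` is n_subjects x V.  Returns the V-vector of t-statistics
    ``t = c'beta / sqrt(sigma^2 c'(X'X)^{-1}c)`` with ``df = n - k``.
    Voxels with zero residual variance get t = 0.
    """
    x = design.columns
    c = design.contrast if contrast is None else np.asarray(contrast, dtype=float)
    n, k = x.shape
    if maps.shape[0] != n:
        raise ValueError(f"maps stack has {maps.shape[0]} rows, design has {n}")
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} subjects, got {n}")
    if np.linalg.matrix_rank(x) < k:
        raise ValueError("rank-deficient design")
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    beta = pinv @ maps
    resid = maps - x @ beta
    df = n - k
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df
    denom = np.sqrt(sigma2 * float(c @ xtx_inv @ c))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (c @ beta) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def t_to_z(t: float | np.ndarray, df: int) -> float | np.ndarray:
    """Convert Student-t statistics to standard-normal equivalents.

    ``z = Phi^{-1}(F_t(t; df))`` evaluated tail-symmetrically in log
    space, so large |t| does not underflow; monotone in t and exactly 0
    at t = 0.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t_arr = np.asarray(t, dtype=float)
    # work on the upper tail of |t|, restore the sign afterwards
    log_sf = stats.t.logsf(np.abs(t_arr), df)
    z_mag = -ndtri_exp(log_sf)
    result = np.sign(t_arr) * z_mag
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(result)
    return result


def r_squared(t: float | np.ndarray, df: int) -> float | np.ndarray:
    """Effect size r^2 = t^2 / (t^2 + df) for a single-contrast t-test."""
    if df < 1:
        raise ValueError("df must be >= 1")
    t_arr = np.asarray(t, dtype=float)
    result = t_arr**2 / (t_arr**2 + df)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(result)
    return result


def cluster_forming_threshold(p_form: float, df: int, one_sided: bool = True) -> float:
    """Critical t for the cluster-forming threshold."""
    alpha = p_form if one_sided else p_form / 2.0
    return float(stats.t.isf(alpha, df))


def form_clusters(
    t_map: np.ndarray,
    df: int,
    p_form: float = 0.001,
    connectivity: int = 18,
    one_sided: bool = True,
) -> list[dict]:
    """Connected supra-threshold clusters of a 3D t-map.

    Thresholds at ``t* = F_t^{-1}(1 - p_form; df)`` (positive contrast)
    and labels connected components under 6/18/26-connectivity.  Returns
    one dict per cluster with voxel indices, extent, and the peak voxel.
    An empty list is a valid result.
    """
    if connectivity not in CONNECTIVITY_STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(CONNECTIVITY_STRUCTURES)}")
    t_star = cluster_forming_threshold(p_form, df, one_sided)
    supra = t_map > t_star
    if one_sided:
        labelled, n_clusters = ndimage.label(supra, structure=CONNECTIVITY_STRUCTURES[connectivity])
    else:
        labelled, n_clusters = ndimage.label(
            supra | (t_map < -t_star), structure=CONNECTIVITY_STRUCTURES[connectivity]
        )
    clusters = []
    for lab in range(1, n_clusters + 1):
        idx = np.argwhere(labelled == lab)
        values = t_map[tuple(idx.T)]
        peak_pos = int(np.argmax(np.abs(values)))
        clusters.append(
            {
                "voxels": idx,
                "extent": int(idx.shape[0]),
                "peak_index": tuple(int(v) for v in idx[peak_pos]),
                "peak_t": float(values[peak_pos]),
            }
        )
    return clusters


def _max_cluster_extent(t_flat, mask, threshold, structure):
    volume = np.zeros(mask.shape, dtype=bool)
    volume[mask] = t_flat > threshold
    labelled, n = ndimage.label(volume, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labelled.ravel())[1:].max())


def cluster_fwe(
    maps: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    p_form: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    connectivity: int = 18,
    one_sided: bool = True,
    batch: int = 50,
) -> pd.DataFrame:
    """Cluster-extent FWE-corrected inference on the interaction contrast.

    Observed clusters are formed from the full-model t-map at ``p_form``;
    the null distribution of the maximum cluster extent comes from
    Freedman-Lane permutations: residuals of the reduced model (the
    design without the interaction column) are row-permuted, the reduced
    fit added back, and the full-model t-map recomputed.  Corrected
    ``p = (1 + #{perm max extent >= observed extent}) / (1 + n_perm)``.

    ``maps`` is n x V over the in-mask voxels of ``mask`` (C-order).
    Returns a DataFrame sorted by corrected p with columns
    ``peak_index, k, t, z, r2, p_fwe, significant``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    n, v = maps.shape
    if v != int(mask.sum()):
        raise ValueError("maps columns do not match mask voxel count")
    if n < 10:
        log.warning("only %d subjects: permutation inference is unreliable below ~10", n)
    if n_perm < 100:
        log.warning("n_perm=%d is low; corrected p-values are coarse below 100", n_perm)

    x = design.columns
    k = x.shape[1]
    df = n - k
    structure = CONNECTIVITY_STRUCTURES[connectivity]
    threshold = cluster_forming_threshold(p_form, df, one_sided)

    t_obs = fit_voxelwise(maps, design)
    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t_obs
    observed = form_clusters(t_vol, df, p_form=p_form, connectivity=connectivity, one_sided=one_sided)

    # Freedman-Lane: permute the reduced-model residuals.  Because the
    # reduced fit lies in the full design's column space, the interaction
    # coefficient and the full-model residual sum of squares of the
    # reconstructed data equal those of the permuted residuals alone, and
    # the per-voxel total sum of squares is permutation-invariant.
    keep = np.flatnonzero(design.contrast == 0)
    x_reduced = x[:, keep]
    resid_reduced = maps - x_reduced @ (np.linalg.pinv(x_reduced) @ maps)

    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)
    pinv_full = xtx_inv @ x.T
    c = design.contrast
    c_scale = float(c @ xtx_inv @ c)
    ss_total = np.einsum("nv,nv->v", resid_reduced, resid_reduced)

    max_extents = np.zeros(n_perm, dtype=int)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm_idx = np.stack([rng.permutation(n) for _ in range(b)])  # (b, n)
        y_perm = resid_reduced[perm_idx]  # (b, n, v)
        beta = np.matmul(pinv_full, y_perm)  # (b, k, v)
        ss_fit = np.einsum("bkv,kl,blv->bv", beta, xtx, beta)
        sigma2 = np.maximum(ss_total[None, :] - ss_fit, 0.0) / df
        denom = np.sqrt(sigma2 * c_scale)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = np.where(denom > 0, np.einsum("k,bkv->bv", c, beta) / np.where(denom > 0, denom, 1.0), 0.0)
        if not one_sided:
            t_perm = np.abs(t_perm)
        for i in range(b):
            max_extents[done + i] = _max_cluster_extent(t_perm[i], mask, threshold, structure)
        done += b

    rows = []
    for cl in observed:
        if n_perm > 0:
            exceed = int(np.sum(max_extents >= cl["extent"]))
            p_corr = (1 + exceed) / (1 + n_perm)
        else:
            p_corr = 1.0
        rows.append(
            {
                "peak_index": cl["peak_index"],
                "k": cl["extent"],
                "t": cl["peak_t"],
                "z": t_to_z(cl["peak_t"], df),
                "r2": r_squared(cl["peak_t"], df),
                "p_fwe": p_corr,
                "significant": p_corr < alpha,
                "voxels": cl["voxels"],
            }
        )
    if n_perm == 0:
        log.warning("n_perm=0: all corrected p-values degenerate to 1")
    table = pd.DataFrame(
        rows, columns=["peak_index", "k", "t", "z", "r2", "p_fwe", "significant", "voxels"]
    )
    if len(table):
        table = table.sort_values("p_fwe", kind="stable").reset_index(drop=True)
    return table


def report_clusters(
    clusters: pd.DataFrame,
    affine: np.ndarray,
    label_volume: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Render a cluster table with mm peak coordinates and region names.

    Peak voxel indices are mapped through ``affine`` (voxel -> mm, so a
    negative x scaling yields radiological-convention coordinates).  When
    an integer label volume and name table are supplied, the peak voxel's
    label names the cluster and the percentage overlap of the cluster
    with each label is given in ``label_overlap``.
    """
    rows = []
    for _, cl in clusters.iterrows():
        idx = np.asarray(cl["peak_index"], dtype=float)
        mm = affine @ np.append(idx, 1.0)
        region = ""
        overlap = ""
        if label_volume is not None:
            if label_volume.ndim != 3:
                raise ValueError("label volume must be 3D")
            voxels = np.asarray(cl["voxels"])
            if (voxels >= np.asarray(label_volume.shape)).any():
                raise ValueError("cluster voxels fall outside the label volume grid")
            peak_label = int(label_volume[tuple(int(v) for v in cl["peak_index"])])
            names = label_names or {}
            region = names.get(peak_label, str(peak_label))
            labels_in = label_volume[tuple(voxels.T)]
            parts = []
            for lab, count in zip(*np.unique(labels_in, return_counts=True)):
                name = names.get(int(lab), str(int(lab)))
                parts.append(f"{name}:{100.0 * count / len(labels_in):.0f}%")
            overlap = ";".join(parts)
        rows.append(
            {
                "region": region,
                "x_mm": float(mm[0]),
                "y_mm": float(mm[1]),
                "z_mm": float(mm[2]),
                "k": int(cl["k"]),
                "t": float(cl["t"]),
                "z": float(cl["z"]),
                "r2": float(cl["r2"]),
                "p_fwe": float(cl["p_fwe"]),
                "label_overlap": overlap,
            }
        )
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS + ["label_overlap"])
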