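"""Nuisance cleaning of 4D BOLD runs.

The chain, in order: despiking, joint OLS regression of (intercept,
linear trend, Friston-24 motion expansion, aCompCor components from
eroded white-matter and CSF masks, global signal), then isotropic
Gaussian smoothing.  All regressors are fitted jointly in a single
model — sequential partial regression would leave shared variance
order-dependent.

The despike operator is a transparent running-median/MAD clip: points
deviating from a kernel-7 running median by more than ``clip_k`` robust
standard deviations are clipped to that bound, all other points pass
through bit-identically.  This is a deterministic stand-in for the
despike step of classical fMRI toolchains, whose exact algorithm varies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceDesign:
    """Assembled t x k nuisance regressor matrix with column labels."""

    columns: np.ndarray
    labels: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def n_regressors(self) -> int:
        return self.columns.shape[1]


def friston24(motion: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body motion parameters to the 24-regressor model.

    Columns 1-6 are the parameters, 7-12 their one-volume lags (first row
    zero-padded), 13-18 the squares of 1-6, and 19-24 the squares of the
    lags.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be t x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, lagged, motion**2, lagged**2])


def erode_mask(mask: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Binary-erode a mask with the full 3x3x3 (26-neighbour) element.

    At 3 mm isotropic voxels this element is one voxel thick in every
    direction.  Raises if the mask erodes to nothing.
    """
    mask = np.asarray(mask).astype(bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    structure = np.ones((3, 3, 3), dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=structure, iterations=iterations)
    if not eroded.any():
        raise ValueError(
            f"mask empty after {iterations} erosion(s); supply a larger mask or fewer iterations"
        )
    return eroded


def acompcor(data: np.ndarray, mask: np.ndarray, n_components: int = 5) -> np.ndarray:
    """Anatomical CompCor: top principal component time courses of a mask.

    Voxel time series inside the mask are linearly detrended and
    variance-normalised; the left singular vectors of the resulting
    time x voxels matrix are returned as t x n_components unit-norm,
    mutually orthogonal time courses ordered by explained variance.  The
    sign of each component is fixed (largest-magnitude sample positive)
    so outputs are deterministic.
    """
    from scipy import signal as sp_signal

    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if n_components == 0:
        return np.zeros((data.shape[-1], 0))
    if not mask.any():
        raise ValueError("empty mask for aCompCor")
    voxels = data[mask]  # (V, t)
    if voxels.shape[0] < n_components:
        raise ValueError(
            f"mask has {voxels.shape[0]} voxels, fewer than n_components={n_components}"
        )
    if not np.all(np.isfinite(voxels)):
        raise ValueError("data contains NaN or Inf inside the aCompCor mask")
    detrended = sp_signal.detrend(voxels, axis=1, type="linear")
    sd = detrended.std(axis=1, ddof=0)
    keep = sd > 0
    if keep.sum() < n_components:
        raise ValueError("too few non-constant voxels in the aCompCor mask")
    normalised = detrended[keep] / sd[keep, None]
    # SVD of (time x voxels); U columns are the component time courses
    u, s, _ = np.linalg.svd(normalised.T, full_matrices=False)
    comps = u[:, :n_components]
    flip = np.sign(comps[np.argmax(np.abs(comps), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    return comps * flip


def global_signal(data: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Per-volume mean signal over in-mask voxels."""
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    return np.asarray(data, dtype=float)[mask].mean(axis=0)


def despike(series: np.ndarray, clip_k: float = 4.0, kernel: int = 7) -> np.ndarray:
    """Clip spikes toward a running-median trend.

    The trend is a running median (reflect-padded, odd ``kernel``); the
    scale is 1.4826x the median absolute deviation of the residuals.
    Points whose residual exceeds ``clip_k`` scales are clipped to
    ``trend +/- clip_k * scale``; all other points are returned unchanged.
    Operates on the last axis, so a (V, t) block despikes every voxel.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    if t < 5:
        raise ValueError("need at least 5 time points to despike")
    half = kernel // 2
    padded = np.concatenate(
        [series[..., half:0:-1], series, series[..., -2 : -half - 2 : -1]], axis=-1
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, kernel, axis=-1)
    trend = np.sort(windows, axis=-1)[..., half]
    resid = series - trend
    mad = np.median(np.abs(resid), axis=-1, keepdims=True)
    scale = 1.4826 * mad
    # constant (zero-MAD) series have no spikes to clip
    limit = np.where(scale > 0, clip_k * scale, np.inf)
    spikes = np.abs(resid) > limit
    out = series.copy()
    out[spikes] = (trend + np.clip(resid, -limit, limit))[spikes]
    return out


def build_nuisance_design(
    n_volumes: int,
    motion: np.ndarray | None = None,
    wm_components: np.ndarray | None = None,
    csf_components: np.ndarray | None = None,
    global_sig: np.ndarray | None = None,
) -> NuisanceDesign:
    """Assemble the joint nuisance design.

    With every block enabled the design has 2 + 24 + 5 + 5 + 1 = 37
    columns: intercept, linear trend, Friston-24 motion, five white-matter
    and five CSF aCompCor components, and the global signal.  Columns that
    are constant-zero or collinear with earlier columns are dropped with a
    warning (all-zero motion files occur in synthetic nulls).
    """
    cols: list[np.ndarray] = [np.ones(n_volumes), np.linspace(-1.0, 1.0, n_volumes)]
    labels: list[str] = ["intercept", "trend"]
    if motion is not None:
        f24 = friston24(motion)
        cols.extend(f24.T)
        base = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        labels += base
        labels += [f"{b}_lag" for b in base]
        labels += [f"{b}_sq" for b in base]
        labels += [f"{b}_lag_sq" for b in base]
    for name, block in (("wm_pc", wm_components), ("csf_pc", csf_components)):
        if block is not None:
            cols.extend(np.asarray(block, dtype=float).T)
            labels += [f"{name}{i + 1}" for i in range(np.asarray(block).shape[1])]
    if global_sig is not None:
        cols.append(np.asarray(global_sig, dtype=float))
        labels.append("global_signal")

    matrix = np.column_stack(cols)
    if matrix.shape[0] != n_volumes:
        raise ValueError("regressor length mismatch")
    kept_idx: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(matrix.shape[1]):
        candidate = matrix[:, kept_idx + [j]]
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            kept_idx.append(j)
            rank = new_rank
        else:
            dropped.append(labels[j])
    if dropped:
        log.warning("dropping %d collinear/zero nuisance columns: %s", len(dropped), dropped)
    return NuisanceDesign(
        columns=matrix[:, kept_idx],
        labels=[labels[j] for j in kept_idx],
        dropped=dropped,
    )


def regress_nuisance(data: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """Per-voxel OLS residuals against the full nuisance design.

    One joint fit; residuals are mean-zero (the intercept is in the
    design) and the voxel mean is not re-added — downstream consumers use
    spectra, which ignore DC.
    """
    data = np.asarray(data, dtype=float)
    x = design.columns
    t = x.shape[0]
    if data.shape[-1] != t:
        raise ValueError(f"data has {data.shape[-1]} volumes, design has {t} rows")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient nuisance design (collinearity drop failed)")
    flat = data.reshape(-1, t)
    # project onto the design's stable range space: near-collinear columns
    # (e.g. lagged slow drifts) would make a normal-equations solve blow up
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = s > s[0] * 1e-10
    basis = u[:, keep]
    resid = flat.T - basis @ (basis.T @ flat.T)
    return resid.T.reshape(data.shape)


def smooth(data: np.ndarray, fwhm_mm: float = 6.0, voxel_size_mm: float = 3.0) -> np.ndarray:
    """Isotropic Gaussian smoothing applied volume-wise.

    ``sigma = fwhm / (2 sqrt(2 ln 2)) / voxel_size`` in voxel units;
    ``fwhm_mm = 0`` is the identity.  Smoothing is unmasked: signal
    bleeds across mask edges as in standard volumetric pipelines.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    data = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return data.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="constant", truncate=6.0)
    # sigma 0 on the time axis: volume-wise smoothing in one pass
    return ndimage.gaussian_filter(
        data, sigma=(sigma_vox,) * 3 + (0.0,), mode="constant", truncate=6.0
    )
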