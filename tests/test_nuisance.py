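"""Nuisance chain operators: Friston-24, erosion, aCompCor, despike, OLS, smoothing."""

import numpy as np
import pytest

from falffpipe.nuisance import (
    acompcor,
    build_nuisance_design,
    despike,
    erode_mask,
    friston24,
    global_signal,
    regress_nuisance,
    smooth,
)


# ---------------------------------------------------------------- friston24
def test_friston24_constant_motion():
    motion = np.tile([1.0, -2.0, 0.5, 0.1, 0.0, 3.0], (10, 1))
    f24 = friston24(motion)
    assert f24.shape == (10, 24)
    # lag columns equal originals except the zero-padded first row
    assert np.allclose(f24[1:, 6:12], motion[1:])
    assert np.all(f24[0, 6:12] == 0)
    assert np.allclose(f24[:, 12:18], motion**2)


def test_friston24_squares_match_direct_multiplication(rng):
    motion = rng.standard_normal((50, 6))
    f24 = friston24(motion)
    assert np.allclose(f24[:, 12], f24[:, 0] ** 2)
    assert np.allclose(f24[:, 18:24], f24[:, 6:12] ** 2)


def test_friston24_rejects_wrong_shape(rng):
    with pytest.raises(ValueError):
        friston24(rng.standard_normal((50, 5)))


# --------------------------------------------------------------- erode_mask
def test_erosion_of_solid_cube():
    cube = np.zeros((7, 7, 7), bool)
    cube[1:6, 1:6, 1:6] = True  # 5x5x5 solid
    once = erode_mask(cube, 1)
    assert once.sum() == 27  # 3x3x3 core
    twice = erode_mask(cube, 2)
    assert twice.sum() == 1  # centre voxel


def test_double_erosion_equals_two_single_erosions(rng):
    ix, iy, iz = np.indices((14, 14, 14))
    blob = (ix - 6.5) ** 2 + (iy - 6.5) ** 2 + (iz - 6.5) ** 2 <= 5.5**2
    blob |= rng.random(blob.shape) > 0.85  # ragged protrusions
    assert np.array_equal(erode_mask(blob, 2), erode_mask(erode_mask(blob, 1), 1))


def test_erosion_to_empty_raises():
    small = np.zeros((5, 5, 5), bool)
    small[2, 2, 2] = True
    with pytest.raises(ValueError, match="larger mask"):
        erode_mask(small, 1)


# ----------------------------------------------------------------- acompcor
def test_acompcor_recovers_shared_time_course(rng):
    t = 100
    shared = np.sin(np.linspace(0, 12, t))
    data = np.zeros((4, 4, 4, t))
    mask = np.zeros((4, 4, 4), bool)
    mask[:3, :3, :3] = True
    data[mask] = shared + 0.01 * rng.standard_normal((mask.sum(), t))
    comps = acompcor(data, mask, n_components=3)
    from scipy.signal import detrend as sp_detrend

    corr = np.corrcoef(comps[:, 0], sp_detrend(shared))[0, 1]
    assert abs(corr) > 0.99


def test_acompcor_components_orthonormal(rng):
    data = rng.standard_normal((5, 5, 5, 60))
    mask = np.ones((5, 5, 5), bool)
    comps = acompcor(data, mask, n_components=5)
    gram = comps.T @ comps
    assert np.allclose(gram, np.eye(5), atol=1e-8)


def test_acompcor_zero_components_empty_block(rng):
    data = rng.standard_normal((3, 3, 3, 40))
    comps = acompcor(data, np.ones((3, 3, 3), bool), n_components=0)
    assert comps.shape == (40, 0)


def test_acompcor_too_few_voxels(rng):
    data = rng.standard_normal((3, 3, 3, 40))
    mask = np.zeros((3, 3, 3), bool)
    mask[0, 0, :2] = True
    with pytest.raises(ValueError, match="fewer"):
        acompcor(data, mask, n_components=5)


# ------------------------------------------------------------ global_signal
def test_global_signal_uniform_volume():
    data = np.full((3, 3, 3, 10), 4.2)
    assert np.allclose(global_signal(data, np.ones((3, 3, 3), bool)), 4.2)


def test_global_signal_single_voxel(rng):
    data = rng.standard_normal((3, 3, 3, 20))
    mask = np.zeros((3, 3, 3), bool)
    mask[1, 2, 0] = True
    assert np.allclose(global_signal(data, mask), data[1, 2, 0])


def test_global_signal_matches_bruteforce(rng):
    data = rng.standard_normal((4, 3, 2, 15))
    mask = rng.random((4, 3, 2)) > 0.4
    expected = np.array([data[..., i][mask].mean() for i in range(15)])
    assert np.allclose(global_signal(data, mask), expected)


# ---------------------------------------------------------------- despike
def test_single_spike_attenuated_others_untouched(rng):
    series = 0.1 * rng.standard_normal(60)
    series[30] += 10.0
    out = despike(series, clip_k=4.0)
    assert abs(out[30]) < abs(series[30])
    untouched = np.delete(np.arange(60), 30)
    assert np.array_equal(out[untouched], series[untouched])


def test_monotone_ramp_passes_through():
    ramp = np.linspace(0.0, 5.0, 40)
    assert np.array_equal(despike(ramp), ramp)


def test_adjacent_spikes_both_attenuated(rng):
    series = 0.1 * rng.standard_normal(80)
    series[40] += 8.0
    series[41] -= 9.0
    out = despike(series, clip_k=4.0)
    assert abs(out[40]) < abs(series[40])
    assert abs(out[41]) < abs(series[41])


def test_despike_batch_matches_per_voxel(rng):
    block = rng.standard_normal((7, 50))
    block[3, 10] += 30.0
    batched = despike(block)
    for i in range(7):
        assert np.allclose(batched[i], despike(block[i]))


# ------------------------------------------------- design / regress_nuisance
def test_full_design_has_37_columns(rng):
    t = 64
    design = build_nuisance_design(
        t,
        motion=rng.standard_normal((t, 6)),
        wm_components=rng.standard_normal((t, 5)),
        csf_components=rng.standard_normal((t, 5)),
        global_sig=rng.standard_normal(t),
    )
    assert design.n_regressors == 37
    assert design.dropped == []


def test_zero_motion_columns_dropped_with_warning(rng, caplog):
    t = 64
    with caplog.at_level("WARNING"):
        design = build_nuisance_design(t, motion=np.zeros((t, 6)))
    assert design.n_regressors == 2  # intercept + trend survive
    assert len(design.dropped) == 24


def test_residuals_orthogonal_to_design(rng):
    t = 80
    design = build_nuisance_design(t, motion=rng.standard_normal((t, 6)))
    data = rng.standard_normal((10, t))
    resid = regress_nuisance(data, design)
    dots = resid @ design.columns
    assert np.abs(dots).max() < 1e-6 * np.abs(data).max() * t


def test_design_column_regressed_to_zero(rng):
    t = 60
    design = build_nuisance_design(t, motion=rng.standard_normal((t, 6)))
    data = np.tile(design.columns[:, 3], (4, 1))
    resid = regress_nuisance(data, design)
    assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(data)


def test_regression_matches_normal_equations(rng):
    t = 50
    design = build_nuisance_design(t, motion=rng.standard_normal((t, 6)))
    data = rng.standard_normal((6, t))
    resid = regress_nuisance(data, design)
    x = design.columns
    beta = np.linalg.solve(x.T @ x, x.T @ data.T)
    assert np.allclose(resid, data - (x @ beta).T, atol=1e-9)


def test_regression_idempotent(rng):
    t = 70
    design = build_nuisance_design(t, motion=rng.standard_normal((t, 6)))
    data = rng.standard_normal((8, t))
    once = regress_nuisance(data, design)
    twice = regress_nuisance(once, design)
    assert np.allclose(once, twice, atol=1e-8)


# ------------------------------------------------------------------ smooth
def test_smooth_fwhm_zero_is_identity(rng):
    data = rng.standard_normal((6, 6, 6, 5))
    assert np.array_equal(smooth(data, fwhm_mm=0.0), data)


def test_smooth_impulse_matches_analytic_gaussian():
    fwhm, voxel = 6.0, 3.0
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
    vol = np.zeros((21, 21, 21))
    vol[10, 10, 10] = 1.0
    out = smooth(vol, fwhm_mm=fwhm, voxel_size_mm=voxel)
    x = np.arange(21) - 10.0
    kernel1d = np.exp(-(x**2) / (2 * sigma**2))
    kernel1d /= kernel1d.sum()
    expected = kernel1d[:, None, None] * kernel1d[None, :, None] * kernel1d[None, None, :]
    assert np.allclose(out, expected, atol=1e-6)


def test_smooth_preserves_interior_mass(rng):
    vol = np.zeros((25, 25, 25, 2))
    vol[12, 12, 12, :] = 1.0
    out = smooth(vol, fwhm_mm=6.0, voxel_size_mm=3.0)
    assert out[..., 0].sum() == pytest.approx(1.0, rel=1e-6)
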