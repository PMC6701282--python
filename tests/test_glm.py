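"""Second-level interaction GLM, t/z/r2 transforms, clustering, permutation FWE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from falffpipe import glm as G
from falffpipe.cohort import CohortTable, SubjectRecord


def make_cohort(low_scores, high_scores):
    records = []
    for i, s in enumerate(low_scores):
        records.append(SubjectRecord(f"l{i}", 60.0 + i % 7, "female" if i % 2 else "male", i % 3, int(s), False, False))
    for i, s in enumerate(high_scores):
        records.append(SubjectRecord(f"h{i}", 55.0 + i % 9, "male" if i % 2 else "female", i % 4, int(s), False, False))
    return CohortTable(records)


@pytest.fixture(scope="module")
def cohort63():
    rng = np.random.default_rng(0)
    return make_cohort(rng.integers(0, 9, 38), rng.integers(9, 31, 25))


# ---------------------------------------------------------------- build_design
def test_design_shape_and_df(cohort63):
    design = G.build_design(cohort63)
    assert design.labels == ["intercept", "group", "score", "group_x_score"]
    assert design.columns.shape == (63, 4)
    assert design.residual_df == 59


def test_design_with_covariates_df(cohort63):
    design = G.build_design(cohort63, covariates=("age", "sex", "nihss"))
    assert design.columns.shape == (63, 7)
    assert design.residual_df == 56
    # covariates are mean-centred
    assert abs(design.columns[:, 4:].mean(axis=0)).max() < 1e-10


def test_design_rejects_single_group():
    cohort = make_cohort([1, 2, 3, 4], [])
    with pytest.raises(ValueError, match="single group"):
        G.build_design(cohort)


def test_design_rejects_collinear_scores():
    # constant score within each group makes score a linear function of
    # group, so the design loses rank
    cohort = make_cohort([5, 5, 5, 5], [9, 9, 9])
    with pytest.raises(ValueError, match="rank"):
        G.build_design(cohort)


# -------------------------------------------------------------- fit_voxelwise
def test_tmap_matches_per_voxel_regression_oracle():
    rng = np.random.default_rng(1)
    cohort = make_cohort(rng.integers(0, 9, 12), rng.integers(9, 25, 8))
    design = G.build_design(cohort)
    maps = rng.standard_normal((20, 20))
    t = G.fit_voxelwise(maps, design)
    x, c = design.columns, design.contrast
    df = design.residual_df
    for v in range(20):
        beta, *_ = np.linalg.lstsq(x, maps[:, v], rcond=None)
        resid = maps[:, v] - x @ beta
        sigma2 = resid @ resid / df
        se = np.sqrt(sigma2 * c @ np.linalg.inv(x.T @ x) @ c)
        assert t[v] == pytest.approx((c @ beta) / se, abs=1e-10)


def test_constructed_interaction_detected(cohort63):
    rng = np.random.default_rng(2)
    design = G.build_design(cohort63)
    interaction = design.columns[:, 3]
    maps = 0.5 * interaction[:, None] + rng.standard_normal((63, 30))
    t = G.fit_voxelwise(maps, design)
    assert t.mean() > 5


def test_null_tmap_is_student_t(cohort63):
    rng = np.random.default_rng(3)
    design = G.build_design(cohort63)
    maps = rng.standard_normal((63, 4000))
    t = G.fit_voxelwise(maps, design)
    pvals = sp_stats.t.sf(t, design.residual_df)
    ks = sp_stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_adding_constant_changes_no_t(cohort63):
    rng = np.random.default_rng(4)
    design = G.build_design(cohort63)
    maps = rng.standard_normal((63, 25))
    t0 = G.fit_voxelwise(maps, design)
    t1 = G.fit_voxelwise(maps + 7.3, design)
    assert np.allclose(t0, t1, atol=1e-9)


def test_group_relabelling_preserves_absolute_t():
    rng = np.random.default_rng(5)
    low = list(rng.integers(0, 9, 10))
    high = list(rng.integers(9, 25, 8))
    cohort = make_cohort(low, high)
    design = G.build_design(cohort)
    maps = rng.standard_normal((18, 15))
    t = G.fit_voxelwise(maps, design)
    # recode group 0<->1: columns [1, 1-g, s, (1-g)s]; the interaction
    # contrast in the recoded basis is the negated original interaction
    x = design.columns
    flipped = np.column_stack([x[:, 0], 1 - x[:, 1], x[:, 2], x[:, 2] - x[:, 3]])
    from dataclasses import replace

    design_f = replace(design, columns=flipped)
    t_f = G.fit_voxelwise(maps, design_f)
    assert np.allclose(np.abs(t), np.abs(t_f), atol=1e-9)


# ------------------------------------------------------------- t_to_z and r2
def test_t_to_z_zero_and_symmetry():
    assert G.t_to_z(0.0, 59) == 0.0
    assert G.t_to_z(-2.5, 30) == pytest.approx(-G.t_to_z(2.5, 30))


def test_t_to_z_limit_matches_normal():
    assert G.t_to_z(1.96, 10**6) == pytest.approx(1.96, abs=1e-3)


def test_t_to_z_monotone_and_stable_for_large_t():
    values = G.t_to_z(np.array([1.0, 3.0, 10.0, 30.0, 100.0]), 40)
    assert np.all(np.diff(values) > 0)
    assert np.isfinite(values).all()


def test_r_squared_range_and_zero():
    assert G.r_squared(0.0, 59) == 0.0
    assert 0 < G.r_squared(5.0, 59) < 1


# ------------------------------------------------------------- form_clusters
def test_single_blob_extent():
    t_map = np.zeros((10, 10, 10))
    t_map[4, 4, 4:9] = 10.0
    clusters = G.form_clusters(t_map, df=30)
    assert len(clusters) == 1
    assert clusters[0]["extent"] == 5


def test_corner_touching_blobs_by_connectivity():
    t_map = np.zeros((8, 8, 8))
    t_map[2, 2, 2] = 9.0
    t_map[3, 3, 3] = 9.0  # touches only at a corner
    assert len(G.form_clusters(t_map, df=30, connectivity=6)) == 2
    assert len(G.form_clusters(t_map, df=30, connectivity=26)) == 1


def flood_fill_clusters(supra, connectivity):
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(supra, dtype=bool)
    sizes = []
    for start in np.argwhere(supra):
        start = tuple(start)
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            pos = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(np.add(pos, off))
                if all(0 <= nb[i] < supra.shape[i] for i in range(3)) and supra[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        sizes.append(size)
    return sorted(sizes)


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_cluster_labels_match_flood_fill(connectivity, rng):
    t_map = rng.standard_normal((12, 12, 12)) * 3
    df = 20
    threshold = G.cluster_forming_threshold(0.001, df)
    clusters = G.form_clusters(t_map, df=df, connectivity=connectivity)
    assert sorted(c["extent"] for c in clusters) == flood_fill_clusters(t_map > threshold, connectivity)


# ---------------------------------------------------------------- cluster_fwe
def test_zero_permutations_degenerate_p(cohort63, caplog):
    rng = np.random.default_rng(6)
    design = G.build_design(cohort63)
    mask = np.ones((4, 4, 4), bool)
    maps = 0.8 * design.columns[:, 3][:, None] + rng.standard_normal((63, 64))
    table = G.cluster_fwe(maps, design, mask, n_perm=0, seed=0)
    if len(table):
        assert (table["p_fwe"] == 1.0).all()


def test_strong_effect_yields_significant_cluster(cohort63):
    rng = np.random.default_rng(7)
    design = G.build_design(cohort63)
    mask = np.ones((6, 6, 6), bool)
    signal = np.zeros((6, 6, 6))
    signal[1:4, 1:4, 1:4] = 1.0
    maps = 0.3 * np.outer(design.columns[:, 3], signal.ravel()) + rng.standard_normal((63, 216))
    table = G.cluster_fwe(maps, design, mask, n_perm=200, seed=1)
    assert len(table) >= 1
    assert bool(table.iloc[0]["significant"])
    assert table.iloc[0]["p_fwe"] <= 1 / (1 + 200) + 1e-12


def test_corrected_p_monotone_in_extent(cohort63):
    rng = np.random.default_rng(8)
    design = G.build_design(cohort63)
    mask = np.ones((8, 8, 8), bool)
    maps = rng.standard_normal((63, 512)) + 0.12 * design.columns[:, 3][:, None] * (
        rng.random(512) > 0.5
    )
    table = G.cluster_fwe(maps, design, mask, n_perm=100, seed=2, p_form=0.01)
    if len(table) >= 2:
        ordered = table.sort_values("k", ascending=False)
        assert ordered["p_fwe"].is_monotonic_increasing


# ------------------------------------------------------------ report_clusters
def _cluster_frame():
    return pd.DataFrame(
        [
            {
                "peak_index": (10, 12, 14),
                "k": 3,
                "t": 5.0,
                "z": 4.6,
                "r2": 0.3,
                "p_fwe": 0.01,
                "significant": True,
                "voxels": np.array([[10, 12, 14], [10, 12, 15], [10, 13, 14]]),
            }
        ]
    )


def test_identity_affine_coordinates():
    report = G.report_clusters(_cluster_frame(), np.eye(4))
    assert (report.loc[0, ["x_mm", "y_mm", "z_mm"]] == [10.0, 12.0, 14.0]).all()


def test_negative_x_scaling_flips_coordinate():
    affine = np.diag([-3.0, 3.0, 3.0, 1.0])
    report = G.report_clusters(_cluster_frame(), affine)
    assert report.loc[0, "x_mm"] == -30.0
    assert report.loc[0, "y_mm"] == 36.0


def test_label_volume_peak_and_overlap():
    labels = np.zeros((20, 20, 20), dtype=int)
    labels[10, 12, 14] = 2
    labels[10, 12, 15] = 2
    labels[10, 13, 14] = 5
    report = G.report_clusters(
        _cluster_frame(), np.eye(4), label_volume=labels, label_names={2: "regionA", 5: "regionB"}
    )
    assert report.loc[0, "region"] == "regionA"
    assert "regionA:67%" in report.loc[0, "label_overlap"]
    assert "regionB:33%" in report.loc[0, "label_overlap"]
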