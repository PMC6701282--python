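"""Synthetic cohort generator: determinism, structure, file round-trips."""

import json

import nibabel as nib
import numpy as np
import pytest

from falffpipe.falff import SLOW4, SLOW5, falff_map
from falffpipe.synth import (
    SyntheticCohortSpec,
    cohort_masks,
    generate_cohort,
    injected_gain,
    iter_cohort,
    load_run,
    spec_from_manifest,
    write_cohort,
)


def test_spec_rejects_short_runs_and_negative_slope():
    with pytest.raises(ValueError):
        SyntheticCohortSpec(n_volumes=32)
    with pytest.raises(ValueError):
        SyntheticCohortSpec(beta_interaction=-0.1)


def test_generation_is_deterministic(tiny_spec):
    cohort_a, runs_a = generate_cohort(tiny_spec)
    cohort_b, runs_b = generate_cohort(tiny_spec)
    assert cohort_a.records == cohort_b.records
    for a, b in zip(runs_a, runs_b):
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.motion, b.motion)
        assert np.array_equal(a.lesion_mask, b.lesion_mask)


def test_iter_cohort_matches_batch_generation(tiny_spec):
    _, runs = generate_cohort(tiny_spec)
    streamed = [run for _, run in iter_cohort(tiny_spec)]
    assert len(streamed) == len(runs)
    for a, b in zip(runs, streamed):
        assert np.array_equal(a.data, b.data)


def test_group_score_distributions_track_published_summaries():
    spec = SyntheticCohortSpec(n_low=38, n_high=25, n_volumes=64, seed=11)
    cohort, _ = next(iter(iter_cohort(spec)))
    low = [r.madrs_total for r in cohort if r.group == "low"]
    high = [r.madrs_total for r in cohort if r.group == "high"]
    assert (len(low), len(high)) == (38, 25)
    assert all(s <= 8 for s in low) and all(s >= 9 for s in high)
    assert np.mean(low) == pytest.approx(2.3, abs=1.5)
    assert np.mean(high) == pytest.approx(14.9, abs=4.0)


def test_masks_structure(tiny_spec, tiny_masks):
    brain, wm, csf, effect = (tiny_masks[k] for k in ("brain", "wm", "csf", "effect"))
    assert not (wm & csf).any()
    assert (wm & ~brain).sum() == 0 and (csf & ~brain).sum() == 0
    assert (effect & ~brain).sum() == 0
    assert not (effect & (wm | csf)).any()


def test_effect_region_outside_brain_rejected():
    with pytest.raises(ValueError, match="outside"):
        cohort_masks(SyntheticCohortSpec(effect_center=(1.0, 1.0, 1.0), effect_radius_vox=5))


def test_lesions_disjoint_from_tissue_masks(tiny_cohort):
    _, _, runs = tiny_cohort
    for run in runs:
        assert not (run.lesion_mask & (run.wm_mask | run.csf_mask)).any()
        assert np.isfinite(run.data).all()


def test_motion_columns_have_requested_sd(tiny_cohort):
    spec, _, runs = tiny_cohort
    for run in runs:
        assert np.allclose(run.motion.std(axis=0), spec.motion_sd, rtol=1e-9)


def test_injected_gain_linear_in_score():
    spec = SyntheticCohortSpec()
    from falffpipe.cohort import SubjectRecord

    scores = np.array([9, 14, 20, 28])
    gains = np.array(
        [injected_gain(spec, SubjectRecord("s", 60.0, "female", 0, int(s), False, False)) for s in scores]
    )
    slope = np.polyfit(scores, gains, 1)[0]
    assert slope == pytest.approx(spec.beta_interaction, rel=1e-9)
    low = injected_gain(spec, SubjectRecord("l", 60.0, "female", 0, 3, False, False))
    assert low == pytest.approx(1.0 + spec.effect_base_gain)


def test_band_specific_amplitude_injection():
    """A slow-5 gain raises raw slow-5 fALFF in the region more than slow-4."""
    spec = SyntheticCohortSpec(n_low=1, n_high=1, seed=5)
    masks = cohort_masks(spec)
    cohort, runs = generate_cohort(spec)
    high_run = [run for rec, run in zip(cohort, runs) if rec.group == "high"][0]
    brain, effect = masks["brain"], masks["effect"]
    bg = brain & ~effect
    diff5 = (
        falff_map(high_run.data, brain, spec.tr_seconds, SLOW5).raw[effect].mean()
        - falff_map(high_run.data, brain, spec.tr_seconds, SLOW5).raw[bg].mean()
    )
    fmap4 = falff_map(high_run.data, brain, spec.tr_seconds, SLOW4).raw
    diff4 = fmap4[effect].mean() - fmap4[bg].mean()
    assert diff5 > 0
    assert diff5 > abs(diff4)


def test_write_cohort_files_and_headers(tmp_path, tiny_cohort):
    spec, cohort, runs = tiny_cohort
    manifest = write_cohort(cohort, runs, spec, tmp_path)
    assert (tmp_path / "cohort.csv").exists()
    for run in runs:
        img = nib.load(str(tmp_path / f"{run.subject_id}_bold.nii"))
        assert img.shape == spec.grid_shape + (spec.n_volumes,)
        assert img.header.get_zooms()[3] == pytest.approx(spec.tr_seconds)
        motion = np.loadtxt(tmp_path / f"rp_{run.subject_id}.txt")
        assert motion.shape == (spec.n_volumes, 6)
    assert len(manifest["files"]) == 4 + 3 * len(runs)


def test_manifest_regeneration_is_bit_identical(tmp_path, tiny_cohort):
    spec, cohort, runs = tiny_cohort
    first = tmp_path / "first"
    write_cohort(cohort, runs, spec, first)
    respec = spec_from_manifest(first / "manifest.json")
    cohort2, runs2 = generate_cohort(respec)
    second = tmp_path / "second"
    write_cohort(cohort2, runs2, respec, second)
    for rel in json.load(open(first / "manifest.json"))["files"]:
        assert (first / rel).read_bytes() == (second / rel).read_bytes(), rel


def test_load_run_round_trip(tmp_path, tiny_cohort):
    spec, cohort, runs = tiny_cohort
    write_cohort(cohort, runs, spec, tmp_path)
    run = load_run(tmp_path, runs[0].subject_id)
    assert run.tr_seconds == pytest.approx(spec.tr_seconds)
    # data stored as float32
    assert np.allclose(run.data, runs[0].data, atol=1e-3 * np.abs(runs[0].data).max())
    assert np.array_equal(run.brain_mask, runs[0].brain_mask)
    assert np.array_equal(run.lesion_mask, runs[0].lesion_mask)
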