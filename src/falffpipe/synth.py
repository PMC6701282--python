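"""Synthetic two-group resting-state cohort generator.

Generates a complete, self-contained study — 4D BOLD runs, tissue and
lesion masks, motion-parameter files and a cohort table — with the
statistical structure the downstream analysis assumes:

* two groups split by the MADRS cut-off (>8), with group score
  distributions matching the published cohort summaries
  (low ~ 2.3 (2.3), high ~ 14.9 (6.7), truncated and rounded),
* per-voxel BOLD = baseline + intrinsic low-frequency oscillations with
  a stable anatomy-like amplitude map + 1/f-coloured and white noise +
  motion-coupled artefact + pulsatile signal in white matter and CSF;
  inside a configurable effect region the oscillation components in the
  effect band are amplified by a gain that grows linearly with the
  symptom score in the high group only — the alternative hypothesis the
  interaction GLM is built to detect,
* schematic tissue geometry: a superellipsoidal brain with white-matter
  and CSF slabs thick enough to survive two erosions, and spherical
  lesions with attenuated signal and extra noise to exercise mask logic
  (the geometry is deliberately schematic, not anatomical),
* rigid-body motion traces whose per-column SD equals ``motion_sd``.

All oscillations are sums of sinusoids at FFT bin centres, so their
spectral mass lands exactly in the intended bins at any run length.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from falffpipe.cohort import CohortTable, SubjectRecord

#: published per-group summaries the score/demographic draws target
GROUP_PARAMS = {
    "low": {"madrs_mean": 2.29, "madrs_sd": 2.31, "age_mean": 64.68, "age_sd": 13.56,
            "p_female": 28 / 38, "nihss_mean": 0.58, "p_history": 0.0, "p_antidep": 1 / 38},
    "high": {"madrs_mean": 14.88, "madrs_sd": 6.67, "age_mean": 59.28, "age_sd": 12.26,
             "p_female": 19 / 25, "nihss_mean": 0.84, "p_history": 6 / 25, "p_antidep": 3 / 25},
}


@dataclass
class SyntheticCohortSpec:
    """Parameters of the synthetic study.

    Defaults mirror the acquisition the generator emulates: TR 3 s,
    140 volumes (7 minutes), 3 mm isotropic voxels; the grid defaults to
    a 24^3 test grid so a full-cohort run completes in minutes, and can
    be raised to the acquisition-scale 72 x 72 x 44.  The effect is a
    spherical region whose effect-band oscillation amplitude is scaled
    by ``1 + effect_base_gain + beta_interaction * score`` for
    high-group subjects (low-group subjects get the base gain regardless
    of score); the defaults roughly double the slow-5 amplitude across
    the high-group score range.
    """

    n_low: int = 38
    n_high: int = 25
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    tr_seconds: float = 3.0
    n_volumes: int = 140
    effect_band: str = "slow5"
    effect_radius_vox: float = 5.0
    effect_center: tuple[float, float, float] | None = None
    beta_interaction: float = 0.06
    effect_base_gain: float = 0.5
    intrinsic_amplitude: float = 3.0
    intrinsic_n_bins: int = 10
    pulsation_amplitude: float = 12.0
    baseline: float = 1000.0
    noise_1f_exponent: float = 1.0
    noise_1f_sd: float = 1.0
    white_noise_sd: float = 3.0
    motion_sd: float = 0.1
    motion_coupling: float = 4.0
    lesion_radius_range: tuple[int, int] = (2, 3)
    lesion_attenuation: float = 0.6
    lesion_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 64:
            raise ValueError("need n_volumes >= 64 to resolve the slow-5 band")
        if self.beta_interaction < 0:
            raise ValueError("beta_interaction must be >= 0")


@dataclass
class BoldRun:
    """One subject's 4D run with its masks and motion trace."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    lesion_mask: np.ndarray
    motion: np.ndarray
    voxel_size_mm: float = 3.0


def cohort_masks(spec: SyntheticCohortSpec) -> dict[str, np.ndarray]:
    """Schematic tissue geometry shared by all subjects.

    Superellipsoidal brain; white matter is a rectangular slab in the
    lower axial third and CSF a mirrored slab in the upper third, both
    disjoint from a centred effect sphere and thick enough to survive
    two 3x3x3 erosions on the default grid.
    """
    nx, ny, nz = spec.grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = 0.42 * nx, 0.42 * ny, 0.42 * nz
    ix, iy, iz = np.indices(spec.grid_shape)
    # superellipsoid (exponent 4): brain-like blob, full enough near the
    # poles that the tissue slabs below keep an erosion-proof core
    brain = (
        ((ix - cx) / rx) ** 4 + ((iy - cy) / ry) ** 4 + ((iz - cz) / rz) ** 4 <= 1.0
    )
    # rectangular tissue slabs: >=5 voxels thick and >=8 wide on the
    # default 24^3 grid, so a core survives two 3x3x3 erosions
    half = (0.16 * nx, 0.16 * ny)
    lateral = (np.abs(ix - cx) <= half[0]) & (np.abs(iy - cy) <= half[1])
    wm = brain & lateral & (iz >= cz - 0.40 * nz) & (iz <= cz - 0.22 * nz)
    csf = brain & lateral & (iz <= cz + 0.40 * nz) & (iz >= cz + 0.22 * nz)
    center = spec.effect_center if spec.effect_center is not None else (cx, cy, cz)
    effect = (
        (ix - center[0]) ** 2 + (iy - center[1]) ** 2 + (iz - center[2]) ** 2
    ) <= spec.effect_radius_vox**2
    if (effect & ~brain).any():
        raise ValueError("effect region extends outside the brain mask")
    # distance to the tissue slabs, used to keep lesions disjoint from them
    tissue_dist = ndimage.distance_transform_edt(~(wm | csf))
    return {"brain": brain, "wm": wm, "csf": csf, "effect": effect, "tissue_dist": tissue_dist}


def _truncated_scores(rng: np.random.Generator, n: int, group: str) -> np.ndarray:
    params = GROUP_PARAMS[group]
    lo, hi = (-0.5, 8.49) if group == "low" else (8.51, 60.49)
    a = (lo - params["madrs_mean"]) / params["madrs_sd"]
    b = (hi - params["madrs_mean"]) / params["madrs_sd"]
    draws = truncnorm.rvs(a, b, loc=params["madrs_mean"], scale=params["madrs_sd"],
                          size=n, random_state=rng)
    return np.clip(np.rint(draws).astype(int), 0 if group == "low" else 9, 60)


def _draw_records(rng: np.random.Generator, spec: SyntheticCohortSpec) -> list[SubjectRecord]:
    records = []
    counter = 0
    for group, n in (("low", spec.n_low), ("high", spec.n_high)):
        params = GROUP_PARAMS[group]
        scores = _truncated_scores(rng, n, group)
        ages = np.clip(rng.normal(params["age_mean"], params["age_sd"], size=n), 20.0, 95.0)
        female = rng.random(n) < params["p_female"]
        nihss = rng.poisson(params["nihss_mean"], size=n)
        history = rng.random(n) < params["p_history"]
        antidep = rng.random(n) < params["p_antidep"]
        for i in range(n):
            counter += 1
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{counter:03d}",
                    age=float(np.round(ages[i], 1)),
                    sex="female" if female[i] else "male",
                    nihss=int(nihss[i]),
                    madrs_total=int(scores[i]),
                    history_depression=bool(history[i]),
                    antidepressant=bool(antidep[i]),
                )
            )
    return records


def band_frequencies(spec: SyntheticCohortSpec, freqs: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask over ``freqs`` for bins inside the effect band.

    With ``freqs`` omitted, all positive FFT bin centres for this run
    length are used.  Raises if the band holds no bins at this length.
    """
    from falffpipe.falff import BROADBAND, SLOW4, SLOW5

    band = {"broadband": BROADBAND, "slow5": SLOW5, "slow4": SLOW4}[spec.effect_band]
    if freqs is None:
        freqs = np.fft.rfftfreq(spec.n_volumes, d=spec.tr_seconds)[1:]
        mask = band.bin_mask(freqs)
        if not mask.any():
            raise ValueError(f"no FFT bins inside band {spec.effect_band!r} at this run length")
        return mask
    return band.bin_mask(np.asarray(freqs))


def intrinsic_frequencies(spec: SyntheticCohortSpec) -> np.ndarray:
    """Bin centres of the intrinsic (anatomy-wide) oscillations.

    Up to ``intrinsic_n_bins`` FFT bins spread log-evenly across the
    0.01-0.08 Hz low-frequency range (low bins over-represented, as in
    real BOLD).  The anatomical fALFF contrast that anchors the global
    z-scoring comes from the spatial balance of these oscillations
    against the broadband noise floor.
    """
    freqs = np.fft.rfftfreq(spec.n_volumes, d=spec.tr_seconds)[1:]
    inside = freqs[(freqs >= 0.01) & (freqs < 0.08)]
    if inside.size <= spec.intrinsic_n_bins:
        return inside
    pick = np.unique(
        np.round(np.geomspace(1, inside.size, spec.intrinsic_n_bins)).astype(int) - 1
    )
    return inside[pick]


def pulsation_frequencies(spec: SyntheticCohortSpec) -> np.ndarray:
    """Bin centres of the pseudo-physiological (pulsatile) oscillations.

    Five FFT bins in the 0.08 Hz-to-Nyquist range, emulating aliased
    respiratory/cardiac pulsation; these dominate white matter and CSF,
    so the aCompCor components they produce carry almost no energy in
    the fALFF numerator bands — the regime in which aCompCor removes
    physiological artefact without degrading band amplitude estimates.
    Five bins, tissue-coherent (below), span ten temporal dimensions —
    exactly the 5+5 components the default aCompCor extracts.
    """
    freqs = np.fft.rfftfreq(spec.n_volumes, d=spec.tr_seconds)[1:]
    nyquist = 0.5 / spec.tr_seconds
    inside = freqs[(freqs >= 0.08) & (freqs <= nyquist)]
    if inside.size <= 5:
        return inside
    pick = np.unique(np.round(np.linspace(0, inside.size - 1, 5)).astype(int))
    return inside[pick]


def intrinsic_amplitude_field(spec: SyntheticCohortSpec, masks: dict[str, np.ndarray]) -> np.ndarray:
    """Cohort-level spatial field of intrinsic oscillation amplitudes.

    A smooth lognormal field (median ``intrinsic_amplitude``) shared by
    all subjects: it plays the role of the stable anatomical structure of
    real fALFF maps, which anchors the global mean and SD used by the
    per-subject z-scoring.  White matter and CSF carry only a small
    fraction of the neural low-frequency signal — which is the premise
    that makes aCompCor valid as a noise model — so the field is strongly
    attenuated inside the tissue slabs.
    """
    field_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB0B0]))
    field = ndimage.gaussian_filter(field_rng.standard_normal(spec.grid_shape), sigma=2.5)
    field = field / field.std()
    amp = spec.intrinsic_amplitude * np.exp(1.0 * field)
    amp[masks["wm"] | masks["csf"]] *= 0.15
    return amp[masks["brain"]]


def white_noise_field(spec: SyntheticCohortSpec, brain: np.ndarray) -> np.ndarray:
    """Cohort-level spatial field of broadband (white) noise SDs.

    Because fALFF is a ratio, a voxel's fALFF is set by the balance of
    its low-frequency oscillation amplitude against its broadband noise
    floor; varying that floor spatially (independently of the intrinsic
    amplitude field) produces the wide, stable anatomical fALFF contrast
    of real maps.
    """
    field_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0C0]))
    field = ndimage.gaussian_filter(field_rng.standard_normal(spec.grid_shape), sigma=2.5)
    field = field / field.std()
    return spec.white_noise_sd * np.exp(1.0 * field)[brain]


def _smooth_phases(
    rng: np.random.Generator, grid_shape: tuple[int, int, int], n_bins: int, flat_mask: np.ndarray
) -> np.ndarray:
    """Per-bin phase fields with ~3-voxel spatial correlation length.

    Long-range incoherence keeps oscillations out of the global signal;
    local coherence lets Gaussian smoothing preserve their amplitude.
    ``flat_mask`` selects the voxels (3D boolean) whose phases are returned.
    """
    field = rng.standard_normal(grid_shape + (n_bins, 2))
    field = ndimage.gaussian_filter(field, sigma=(3.0, 3.0, 3.0, 0.0, 0.0))
    return np.arctan2(field[..., 1], field[..., 0])[flat_mask]


def _band_waveforms(
    times: np.ndarray, freqs: np.ndarray, phases: np.ndarray
) -> np.ndarray:
    """Unit-SD sum of sinusoids at ``freqs`` with per-voxel ``phases`` (V, F)."""
    angles = 2 * np.pi * times[None, None, :] * freqs[None, :, None]
    waveform = np.sin(angles + phases[:, :, None]).sum(axis=1)
    return waveform / np.sqrt(freqs.size / 2.0)


def injected_gain(spec: SyntheticCohortSpec, record: SubjectRecord) -> float:
    """Amplitude gain applied to effect-band oscillations for one subject.

    Inside the effect region the intrinsic oscillation components whose
    frequencies fall in the effect band are multiplied by
    ``1 + effect_base_gain + beta_interaction * score`` (the score term
    only in the high group).  A multiplicative gain — rather than an
    independent additive oscillation — models an up-regulated intrinsic
    fluctuation, and keeps the injected spectral mass phase-locked to
    the voxel's own oscillation.
    """
    gain = 1.0 + spec.effect_base_gain
    if record.group == "high":
        gain += spec.beta_interaction * record.madrs_total
    return gain


def spectral_exponent_field(spec: SyntheticCohortSpec, brain: np.ndarray) -> np.ndarray:
    """Cohort-level spatial field of 1/f exponents, one value per brain voxel.

    Real fALFF maps have strong, stable anatomical structure (tissue-class
    and regional differences), which anchors the global mean/SD that the
    per-subject z-scoring divides by.  The generator emulates this with a
    smooth random field of spectral exponents centred on
    ``noise_1f_exponent`` (+/- 0.5), shared by every subject and derived
    deterministically from the cohort seed.
    """
    field_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA11A]))
    field = ndimage.gaussian_filter(field_rng.standard_normal(spec.grid_shape), sigma=2.5)
    field = field / field.std()
    exponents = spec.noise_1f_exponent + 0.5 * np.tanh(field)
    return exponents[brain]


def _one_over_f_noise(
    rng: np.random.Generator,
    exponents: np.ndarray,
    spec: SyntheticCohortSpec,
) -> np.ndarray:
    t = spec.n_volumes
    n_voxels = exponents.shape[0]
    white = rng.standard_normal((n_voxels, t))
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(t, d=spec.tr_seconds)
    weights = np.zeros((n_voxels, freqs.size))
    weights[:, 1:] = freqs[None, 1:] ** (-exponents[:, None] / 2.0)
    shaped = np.fft.irfft(spectrum * weights, n=t, axis=-1)
    sd = shaped.std()
    return shaped * (spec.noise_1f_sd / sd)


def _motion_trace(rng: np.random.Generator, spec: SyntheticCohortSpec) -> np.ndarray:
    """Rigid-body trace: slow drift plus volume-to-volume jitter.

    Realignment parameters are modelled as respiratory jitter (a
    narrow 0.10-0.14 Hz band — breathing at ~0.25-0.30 Hz aliased by
    the 3 s sampling — carrying 75% of the variance) riding on a slow
    drift (time scale ~10 volumes, whose energy sits below the fALFF
    numerator bands).  Both the jitter band and the alias of its second
    harmonic, which appears in the squared Friston regressors, stay
    clear of the slow-5 band.  Each column is rescaled so its SD is
    exactly ``motion_sd``.
    """
    t = spec.n_volumes
    drift = ndimage.gaussian_filter1d(
        rng.standard_normal((t, 6)), sigma=10.0, axis=0, mode="reflect"
    )
    drift /= drift.std(axis=0, ddof=0)
    white = rng.standard_normal((t, 6))
    spectrum = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(t, d=spec.tr_seconds)
    spectrum[(freqs < 0.12) | (freqs > 0.13)] = 0
    jitter = np.fft.irfft(spectrum, n=t, axis=0)
    jitter /= jitter.std(axis=0, ddof=0)
    mixed = np.sqrt(0.25) * drift + np.sqrt(0.75) * jitter
    return mixed * (spec.motion_sd / mixed.std(axis=0, ddof=0))


def _generate_run(
    rng: np.random.Generator,
    spec: SyntheticCohortSpec,
    record: SubjectRecord,
    masks: dict[str, np.ndarray],
) -> BoldRun:
    brain = masks["brain"]
    n_vox = int(brain.sum())
    t = spec.n_volumes

    series = np.full((n_vox, t), spec.baseline)
    series += _one_over_f_noise(rng, masks["exponents"], spec)
    series += masks["white_sd"][:, None] * rng.standard_normal((n_vox, t))
    times = np.arange(t) * spec.tr_seconds

    # intrinsic low-frequency oscillations with an anatomy-like amplitude
    # map; inside the effect region the components in the effect band are
    # amplified by the subject's score-dependent gain
    if "intrinsic_base" in masks:
        series += masks["intrinsic_base"]
        band_part = masks["intrinsic_band_effect"]
        if band_part is not None:
            effect_flat = masks["effect"][brain]
            series[effect_flat] += (injected_gain(spec, record) - 1.0) * band_part

    # pulsatile physiological signal dominating white matter and CSF
    # pulsatile signal in white matter and CSF: one phase per bin per
    # subject plus a per-voxel offset, so the pulsation spans exactly the
    # ten temporal dimensions (5 bins x sin/cos) that the 5+5 default
    # aCompCor components extract — the components come out as clean
    # high-band regressors rather than white-noise directions
    pulse_freqs = pulsation_frequencies(spec)
    tissue = (masks["wm"] | masks["csf"])[brain]
    if spec.pulsation_amplitude > 0 and pulse_freqs.size and tissue.any():
        n_tissue = int(tissue.sum())
        phases = (
            rng.uniform(0, 2 * np.pi, size=pulse_freqs.size)[None, :]
            + rng.uniform(0, 2 * np.pi, size=n_tissue)[:, None]
        )
        series[tissue] += spec.pulsation_amplitude * _band_waveforms(times, pulse_freqs, phases)

    motion = _motion_trace(rng, spec)
    loadings = spec.motion_coupling * rng.standard_normal((6, n_vox))
    series += (motion @ loadings).T

    # spherical lesion with attenuated signal and extra noise; centres are
    # kept clear of the tissue slabs so wm/csf stay disjoint from lesions
    radius = int(rng.integers(spec.lesion_radius_range[0], spec.lesion_radius_range[1] + 1))
    centres = np.argwhere(brain & (masks["tissue_dist"] > radius + 0.5))
    centre = centres[int(rng.integers(len(centres)))]
    ix, iy, iz = np.indices(spec.grid_shape)
    lesion = ((ix - centre[0]) ** 2 + (iy - centre[1]) ** 2 + (iz - centre[2]) ** 2) <= radius**2
    lesion &= brain
    lesion_flat = lesion[brain]
    if lesion_flat.any():
        series[lesion_flat] = (
            spec.baseline
            + spec.lesion_attenuation * (series[lesion_flat] - spec.baseline)
            + spec.lesion_noise_sd * rng.standard_normal((int(lesion_flat.sum()), t))
        )

    data = np.zeros(spec.grid_shape + (t,))
    data[brain] = series
    return BoldRun(
        subject_id=record.subject_id,
        data=data,
        tr_seconds=spec.tr_seconds,
        brain_mask=brain,
        wm_mask=masks["wm"],
        csf_mask=masks["csf"],
        lesion_mask=lesion,
        motion=motion,
        voxel_size_mm=spec.voxel_size_mm,
    )


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[CohortTable, list[BoldRun]]:
    """Generate the cohort table and one BOLD run per subject.

    Deterministic given ``spec.seed``: the same spec always produces
    bit-identical arrays.
    """
    records = None
    runs = []
    for cohort, run in iter_cohort(spec):
        records = cohort
        runs.append(run)
    return records, runs


def iter_cohort(spec: SyntheticCohortSpec):
    """Stream ``(cohort_table, run)`` pairs one subject at a time.

    Yields the same runs as :func:`generate_cohort` (identical random
    stream) without holding the whole cohort in memory — at
    acquisition-scale grids a single 4D run is ~100 MB, so large-cohort
    pipelines should consume runs one by one.
    """
    rng = np.random.default_rng(spec.seed)
    masks = cohort_masks(spec)
    masks["exponents"] = spectral_exponent_field(spec, masks["brain"])
    masks["intrinsic_amp"] = intrinsic_amplitude_field(spec, masks)
    masks["white_sd"] = white_noise_field(spec, masks["brain"])
    # the intrinsic oscillation pattern — amplitudes AND phases — is a
    # property of the cohort's shared anatomy: fALFF maps of real
    # subjects are highly reproducible, and per-subject phase draws
    # would make narrowband synthetic amplitude maps fluctuate far more
    # between subjects than real test-retest data do
    field_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD0D0]))
    intrinsic_freqs = intrinsic_frequencies(spec)
    masks["intrinsic_phases"] = _smooth_phases(
        field_rng, spec.grid_shape, intrinsic_freqs.size, masks["brain"]
    )
    # the intrinsic oscillation is cohort-level, so synthesise it once
    if spec.intrinsic_amplitude > 0 and intrinsic_freqs.size:
        times = np.arange(spec.n_volumes) * spec.tr_seconds
        norm = np.sqrt(intrinsic_freqs.size / 2.0)
        amp = masks["intrinsic_amp"] / norm
        phases = masks["intrinsic_phases"]
        base = np.zeros((amp.size, spec.n_volumes))
        in_band = band_frequencies(spec, intrinsic_freqs)
        effect_flat = masks["effect"][masks["brain"]]
        band_effect = np.zeros((int(effect_flat.sum()), spec.n_volumes)) if effect_flat.any() else None
        for j, freq in enumerate(intrinsic_freqs):
            component = amp[:, None] * np.sin(
                2 * np.pi * freq * times[None, :] + phases[:, j, None]
            )
            base += component
            if in_band[j] and band_effect is not None:
                band_effect += component[effect_flat]
        masks["intrinsic_base"] = base
        masks["intrinsic_band_effect"] = band_effect
    cohort = CohortTable(_draw_records(rng, spec))
    for record in cohort:
        yield cohort, _generate_run(rng, spec, record, masks)


def _save_nifti(path: Path, array: np.ndarray, affine: np.ndarray, tr: float | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    if tr is not None:
        img.header.set_zooms(img.header.get_zooms()[:3] + (tr,))
        img.header["xyzt_units"] = 10  # mm + sec
    img.to_filename(str(path))


def write_cohort(
    cohort: CohortTable,
    runs: list[BoldRun],
    spec: SyntheticCohortSpec,
    dest: str | Path,
) -> dict:
    """Write a generated cohort to disk and return the manifest.

    Layout: ``cohort.csv``, ``manifest.json``, shared tissue masks under
    ``masks/``, and per subject ``<id>_bold.nii``, ``rp_<id>.txt`` (six
    whitespace-separated columns, one row per volume) and
    ``<id>_lesion.nii``.  Uncompressed NIfTI-1 is used so regeneration
    from the manifest reproduces every file bit-identically.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    (dest / "masks").mkdir(exist_ok=True)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])

    cohort.to_csv(dest / "cohort.csv")
    masks = cohort_masks(spec)
    for name in ("brain", "wm", "csf"):
        _save_nifti(dest / "masks" / f"{name}_mask.nii", masks[name].astype(np.uint8), affine)

    files = ["cohort.csv", "masks/brain_mask.nii", "masks/wm_mask.nii", "masks/csf_mask.nii"]
    for run in runs:
        bold_name = f"{run.subject_id}_bold.nii"
        _save_nifti(dest / bold_name, run.data, affine, tr=run.tr_seconds)
        lesion_name = f"{run.subject_id}_lesion.nii"
        _save_nifti(dest / lesion_name, run.lesion_mask.astype(np.uint8), affine)
        motion_name = f"rp_{run.subject_id}.txt"
        np.savetxt(dest / motion_name, run.motion, fmt="%.8e")
        files += [bold_name, lesion_name, motion_name]

    manifest = {"spec": asdict(spec), "seed": spec.seed, "files": files}
    with open(dest / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def spec_from_manifest(path: str | Path) -> SyntheticCohortSpec:
    """Rebuild the generator spec from a written manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    raw = dict(manifest["spec"])
    for key in ("grid_shape", "lesion_radius_range"):
        raw[key] = tuple(raw[key])
    if raw.get("effect_center") is not None:
        raw["effect_center"] = tuple(raw["effect_center"])
    return SyntheticCohortSpec(**raw)


def load_run(directory: str | Path, subject_id: str) -> BoldRun:
    """Load one subject's run (data, masks, motion) from a written cohort."""
    directory = Path(directory)
    bold = nib.load(str(directory / f"{subject_id}_bold.nii"))
    data = np.asarray(bold.dataobj, dtype=float)
    zooms = bold.header.get_zooms()
    masks = {}
    for name in ("brain", "wm", "csf"):
        masks[name] = np.asarray(
            nib.load(str(directory / "masks" / f"{name}_mask.nii")).dataobj
        ).astype(bool)
    lesion = np.asarray(nib.load(str(directory / f"{subject_id}_lesion.nii")).dataobj).astype(bool)
    motion = np.loadtxt(directory / f"rp_{subject_id}.txt")
    return BoldRun(
        subject_id=subject_id,
        data=data,
        tr_seconds=float(zooms[3]) if len(zooms) > 3 else 3.0,
        brain_mask=masks["brain"],
        wm_mask=masks["wm"],
        csf_mask=masks["csf"],
        lesion_mask=lesion,
        motion=motion,
        voxel_size_mm=float(zooms[0]),
    )
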