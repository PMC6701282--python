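# Methods notes

## The measure

fALFF at voxel v for band B = [lo, hi) is

    fALFF_B(v) = Σ_{lo ≤ f < hi} |X_v(f)|  /  Σ_{0 < f ≤ f_Nyq} |X_v(f)|

where |X_v(f)| is the one-sided amplitude spectrum of the voxel's
linearly detrended time series.  Amplitude is the square root of power;
because the same constant scales numerator and denominator, the ratio is
invariant to the |FFT| vs √(|FFT|²/T) convention (tested).  Bins are
half-open [lo, hi): the bin at exactly 0.027 Hz belongs to slow-4, is
never double counted, and the DC bin is excluded everywhere while the
Nyquist bin counts toward the denominator.  The denominator runs to the
Nyquist frequency (0.167 Hz at TR 3 s); a nominal upper bound of
~0.33 Hz sometimes quoted for this acquisition cannot be realised at
this sampling rate and is not attempted.  Default bands: broadband
0.01–0.08 Hz, slow-5 0.01–0.027 Hz, slow-4 0.027–0.07 Hz.  With TR 3 s,
slow-5 requires ≥ ~64 volumes to contain any FFT bin; `falff()` raises
with the minimum length when a band is empty.  No taper is applied
(only the linear detrend); constant series return fALFF 0 with a
warning rather than an error.

Maps are z-scored per subject by the global in-mask mean and SD.  This
standardisation decouples amplitudes from scanner scaling and motion
burden, but couples every voxel to the whole-brain distribution — a
property with real consequences for simulated effects (below).

## Cleaning chain

Order: despike → joint nuisance OLS → 6 mm Gaussian smoothing; fALFF
consumes the smoothed residuals.  All 37 regressors (intercept, linear
trend, Friston-24 motion expansion, 5 WM + 5 CSF aCompCor components
from masks thresholded at 0.99 and twice eroded with the full 3×3×3
element, global signal) are fitted in a single model; sequential partial
regression would make shared variance order-dependent.  Projection uses
a rank-truncated SVD so near-collinear columns (e.g. lagged slow drifts)
cannot amplify rounding noise; exactly collinear or all-zero columns are
dropped with a warning beforehand.  Global-signal regression and
despiking are config flags (default on).

The despike operator is deliberately transparent: residuals from a
kernel-7 running median are clipped at ±4 robust SDs (1.4826·MAD);
unclipped samples pass through bit-identically.  Classical fMRI
toolchains implement despiking with varying, partly undocumented
algorithms; this operator has the same intent and is fully testable.
Slice-timing correction and realignment are not implemented — input data
are expected already aligned on a common grid (the synthetic generator
produces them that way).

## Second-level model and inference

Per voxel, z-scored fALFF is regressed on [1, group, score,
group × score] (group: low = 0/high = 1; score not centred, so the
interaction column carries the conventional parameterisation; optional
mean-centred age/sex/NIHSS covariates).  The interaction t-statistic
uses df = n − k.  Clusters form at one-sided p < 0.001 under
18-connectivity (configurable 6/18/26) and their extents are referred to
the permutation distribution of the maximum cluster extent, obtained by
Freedman–Lane shuffling of reduced-model residuals — the standard scheme
for permuting one term of a multiple regression.  Corrected
p = (1 + b)/(1 + m) never reaches zero and the test is exact at any
permutation count.  This replaces random-field-theory cluster FWE: at
the same thresholds, permutation gives exact control without smoothness
estimation, but corrected p-values are not numerically comparable to
RFT ones.  An implementation note: because the reduced-model fit lies in
the full design's column space, the permuted interaction coefficient and
residual sum of squares can be computed from the permuted residuals
alone, and the residual total sum of squares is permutation-invariant —
the permutation loop therefore needs one matrix product per batch.

t→z conversion is Φ⁻¹(F_t(t; df)) evaluated tail-symmetrically in log
space (`ndtri_exp`), stable for |t| far beyond any realistic map value.
The effect size is r² = t²/(t²+df); the sometimes-quoted radical form
√t²/(t²+df) is not monotone-consistent with the published values this
formula reproduces, so the plain ratio is used.

## Cohort statistics

Welch's unequal-variance t-test (forced by the non-integer dfs the study
reports) with Satterthwaite df, computable from printed n/mean/SD
summaries.  2×2 comparisons use Pearson χ² without continuity correction
(the convention that reproduces the published statistics) and
Monte-Carlo p-values from fixed-margin reshuffles (hypergeometric null,
(1+b)/(1+m) estimator).  Three published item-level χ² values (reported
sadness 5.99, discouragement 7.58, loss of interest 7.72) and the sex
comparison (0.67) cannot be reconciled with the printed yes/no counts
under any standard 2×2 convention we tried (the counts give e.g. 0.04
for sex); these are excluded from validation.

## Synthetic cohort generator

The generator emulates the data *structure* the analysis assumes, not
brain anatomy.  Per subject, each in-brain voxel receives:

* baseline 1000 (arbitrary EPI units);
* intrinsic low-frequency oscillations: sums of sinusoids at ~10
  log-spaced FFT bins in 0.01–0.08 Hz.  Their amplitude map (lognormal,
  median 3, smooth at ~2.5 voxels), the white-noise SD map (lognormal
  around 3) and a 1/f-exponent map (1.0 ± 0.5) are *cohort-level* smooth
  random fields: they play the role of the stable anatomical fALFF
  contrast of real brains, which anchors the global z-scoring.  The
  oscillation phase fields (correlation length ~3 voxels) are also
  cohort-level: spatial incoherence at long range keeps the oscillations
  out of the global signal, local coherence lets the 6 mm smoothing
  preserve their amplitude, and sharing them across subjects reproduces
  the high between-subject reproducibility of real amplitude maps that
  narrowband per-subject phase draws cannot give;
* 1/f-coloured noise (SD 1) and white noise (spatially varying SD);
* motion artefact: six rigid-body traces (SD exactly `motion_sd` = 0.1),
  modelled as narrowband 0.12–0.13 Hz jitter (breathing at ~0.25–0.29 Hz
  aliased by the 3 s sampling; 75% of variance) over a slow ~10-volume
  drift, coupled into voxels through random loadings.  The narrow band
  is chosen so that neither the jitter, nor the alias of its second
  harmonic that appears in the squared Friston regressors, overlaps the
  slow-5 band — otherwise the 24-column motion projection removes or
  injects slow-5 amplitude at random per subject;
* WM/CSF pulsation: five bins at 0.08 Hz–Nyquist with a per-voxel phase
  offset, spanning exactly the ten temporal dimensions the 5 + 5
  aCompCor components extract, so the components come out as clean
  high-band regressors (the premise under which aCompCor removes
  physiology without degrading band estimates);
* a spherical lesion (radius 2–3 voxels, signal attenuated ×0.6, extra
  noise SD 2) placed so it never intersects the WM/CSF slabs;
* the effect: inside a radius-5 sphere at the brain centre, the
  slow-5-band oscillation components are multiplied by the gain
  1 + 0.5 + 0.06·score for high-group subjects (1.5 for everyone else) —
  roughly an amplitude doubling across the observed high-group score
  range.  A multiplicative gain on the voxel's own oscillation models an
  up-regulated intrinsic fluctuation; an *additive* independent
  oscillation is destroyed either by GSR (if spatially coherent) or by
  smoothing (if phase-incoherent).

Geometry is schematic: a superellipsoidal "brain" (exponent 4, radii
0.42 × grid), rectangular WM/CSF slabs in the lower/upper axial thirds
(thick enough that a core survives two erosions on the default 24³
grid).  MÅDRS scores are truncated-normal draws matching the published
group means/SDs (low ≈ 2.3 (2.3), high ≈ 14.9 (6.7)), rounded to
integers and constrained to the ≤8 / >8 split; ages, sex, NIHSS and
history/antidepressant flags follow the published group frequencies.
Everything is deterministic given the seed; `iter_cohort` streams
subjects for memory-bounded large-grid runs, and `write_cohort` emits
uncompressed NIfTI-1 + SPM-style `rp_*.txt` files that regenerate
bit-identically from the JSON manifest.

What the generator does **not** emulate: haemodynamic response shape,
physiological waveforms beyond schematic pulsation, EPI distortion,
slice timing, realistic lesion pathology, and — importantly —
broadband biological fluctuations with subject-specific phase but
stable amplitude.  Passing tests therefore show the pipeline's
operators, calibration and determinism are correct; they do not certify
sensitivity on real data.

## Problem sizes used by the validation experiments

The null calibration uses 200 cohorts of 12 + 8 subjects on the 24³
grid with 64-volume runs and 500 permutations each.  The recovery
experiment uses 20 replicate cohorts at the default study conditions
(38 + 25 subjects, 24³ grid) with 100-volume runs, both sub-bands, and
200 permutations.  The end-to-end determinism check runs 3 + 3 subjects
twice and compares output bytes.

## Known limitation: recovery power at simulation scale

With the full chain the injected slow-5 effect is reliably visible in
*raw* fALFF maps (per-voxel interaction t ≈ 3.5 at n = 63 before
cleaning) but rarely survives to a corrected-significant cluster.  Four
compounding mechanisms, each quantified by fixed-score replicate
experiments, are responsible: (1) global z-scoring caps a region
occupying fraction p of the brain at about 1/√p global SDs — a radius-5
sphere is ~8% of a 24³-grid brain, so the usable score slope saturates
(in real data significant clusters are ≲0.1% of the brain and this
ceiling is irrelevant); (2) projecting out 37 nuisance regressors from
140-volume series removes/injects band amplitude by chance alignment;
(3) smoothing dilutes the region boundary; (4) GSR removes the
score-scaled coherent share of the region's band signal.  The slow-4
analysis stays appropriately silent (band specificity holds), and the
familywise-error calibration is unaffected — the test controls its
error rate regardless of power.  The recovery experiment is still run
and reported honestly by `scripts/acceptance.py`.
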