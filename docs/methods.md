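# Methods

This note records the scientific model behind `nordiceval`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Noise model and denoising

Thermal noise in the complex MR signal is zero-mean Gaussian per channel,
spatially scaled by the parallel-imaging g-factor.  After dividing by an
estimated g-map the noise is (ideally) i.i.d. across voxels, so a patch's
Casorati matrix (M patch voxels × N timepoints) is "low-rank signal +
i.i.d. noise".  Pure-noise singular values concentrate below the
Marchenko–Pastur bulk edge; components at or below a cutoff estimated by
Monte Carlo (mean largest singular value over 20 draws of an M×N matrix
with i.i.d. N(0, σ²) entries, run once at σ=1 and scaled — hence exactly
equivariant in σ) are zeroed.  Hard thresholding, not shrinkage: removed
components are considered noise outright.  Complex data enter the
real-matrix Monte Carlo through the per-entry standard deviation (√2 ×
per-component σ); the bulk edge depends only on the entry variance.

Patch geometry: cubic kernel with side ≈ (11 × N)^{1/3} clipped to the
volume, stride of half a side, with boundary patches shifted inward so
every voxel is covered; overlapping reconstructions are averaged
unweighted.  With the cutoff forced to zero this machinery is exactly the
identity, which the tests use to validate the patch bookkeeping.

### Threshold calibration

- `noise_scan` mode: σ̂ is pooled from the appended no-excitation volumes
  after g-normalization.  Per-voxel variances use ddof=1: with the usual
  five noise scans, the biased estimator would lower σ̂ by ~10 % and with
  it the cutoff, leaving a shell of noise components untouched.
- `gfactor_only` mode: σ̂ comes from first temporal differences of the
  series and the cutoff is scaled by 1/√2.  The constant is exposed as
  configuration (`cutoff_scale`); it makes this mode systematically
  conservative — it removes fewer components than the noise-scan mode on
  identical data, which the test suite asserts.

### g-factor estimation

With ≥ 50 noise scans (≥ 100 scalar samples/voxel) the spatial map is the
voxelwise std of the noise-scan values.  With the realistic handful of
noise scans, a per-voxel std over ~10 samples is so uncertain that after
normalization the residual spatial non-uniformity pushes dozens of noise
components past the threshold; the spatial pattern is therefore estimated
from high-frequency temporal differences of the *data* volumes (hundreds
of samples per voxel), while the noise scans calibrate only the absolute
σ.  Noise scans are excluded from the differences — the signal→
no-excitation step at the boundary would otherwise dominate the estimate.
Smoothing of the map is adaptive: a heavily smoothed copy (σ = 1.5 vox)
first tests for spatial structure; near-flat maps are smoothed at 1.5 vox
(pure estimation noise), structured maps at 0.4 vox (well-sampled) or
1.0 vox (sparse), because heavier smoothing visibly flattens real g
gradients and skews the subsequent normalization to minimum 1.

### Phase handling

Magnitude+phase input is preferred; magnitude-only data carry Rician
noise, which the Gaussian threshold model only approximates (the package
runs magnitude-only, with this caveat).  Phase stabilization removes a
volume-specific low-spatial-frequency phase: the k-space window is the
full-taper Tukey (= Hann) profile evaluated on the FFT frequency grid and
raised to the scale factor (default 10), which keeps it exactly 1 at DC
and even-symmetric for any grid size; the data are rotated by the
conjugate unit phase of the low-pass image, leaving the magnitude
untouched.

## Analysis chain

Noise scans are stripped before analysis.  Temporal filtering = Fourier
removal of cycles 1–6 per run (mean retained) followed by a temporal
Gaussian of FWHM 2 volumes; filtering precedes PSC normalization (the
order is not otherwise constrained; fixing it keeps strategies
comparable).  The GLM has one regressor per trial — the two-gamma HRF
(gamma-density difference, unit scale; positive lobe peaking at 5 s,
undershoot peaking near 15 s at 1/6 amplitude, kernel normalized to unit
sum) sampled at the TR and shifted to the onset — plus a constant.  With a
unit-sum kernel, betas are percent signal change.  The t statistic is the
one-sample t across single-trial betas (mean/(sd/√n), dof = n−1): a
description of this statistic as "mean divided by variance" is
dimensionally inconsistent with t-distribution thresholds, so the standard
t is used.  FDR maps are two-sided p-values under the t distribution with
Benjamini–Hochberg step-up (BH, not BY).

Reliability: Pearson correlations of maps over a mask; random split-half
with 50 repetitions (odd run counts split n//2 vs the rest); run-to-run
over all unordered pairs; leave-one-run-out against the average of the
*original* runs (the reference never comes from denoised data).
Correlations are clipped to |r| ≤ 1−10⁻¹² before Fisher-z averaging.
Group inference: repeated-measures ANOVA (pingouin) with
Greenhouse–Geisser correction, exhaustive 2^n sign-flip permutation tests
(two-sided; resolution exactly 2^{-n}), Bonferroni adjustment.

Variance partitioning is per run (per-voxel OLS of the original on the
denoised series plus intercept).  The OLS identity
SS_total = α²·SS_AN + SS_resid is exact and asserted at 10⁻⁸ relative
tolerance; voxels whose denoised series is near-constant are excluded with
a count rather than fitted.  All sums of squares are about sample means.

Laminar profiles average single-trial betas over the ROI voxels of each of
11 depth bins, then take mean and sd across trials.  Depth sampling is
volumetric (integer labels from the simulator); vertex-wise equivolume
surface sampling is out of scope, so profiles are an approximation of
interpolate-then-average surface pipelines.  Best-frequency maps label
each significant voxel by the larger of the two predictable-condition
betas; ties (|Δβ| < 10⁻⁹) are untuned.

## The synthetic generator

Defaults are the study conditions: 230 volumes at TR 1.6 s plus 5
appended noise scans; six conditions with 10/10/4/4/4/4 trials per run;
inter-trial intervals a seeded permutation of equally many 5s and 7s with
6s filling the remainder, so the mean is exactly 6 volumes (36 onsets have
35 gaps, hence 12/11/12); 6 lead-in and ≥ 6 lead-out baseline volumes.  A
second site differing only in TR (1.65 s) is supported via configuration.

Noise and signal scales (chosen once, as a realistic operating point for
low-SNR laminar fMRI, and documented here rather than revisited):
baseline 100 a.u.; thermal σ = 1.5 per complex component; g-factor a
smooth field in (1.0, 2.5); structured physiological noise of ~1 % —
linear drift, respiratory-like (0.3 Hz) and cardiac-like (1 Hz, aliased)
sinusoids with smooth spatial weight maps, and an AR(1) term (ρ = 0.3)
with spatially smoothed innovations.  The spatial coherence of the AR term
matters: physiological fluctuations in real data are structured, and a
voxelwise-independent AR term would be statistically indistinguishable
from extra thermal noise, inflating the singular-value bulk just past the
calibrated threshold.  Responses average 2.5 % PSC with a wide smooth
spatial spread (relative sd 1.0 — activation maps span roughly 0–6 % with
vascular contributions), a deep→superficial amplitude ramp (0.6×–1.6×, the
GE-BOLD draining-vein gradient) over 11 depth bins, and a low/high/low
frequency-preference band pattern scaling conditions ending in the
preferred target frequency by 1±0.4.  Phase is a smooth static field plus
a small slow temporal modulation.

What the generator does *not* emulate: k-space sampling and
reconstruction, multiband/SENSE aliasing, motion, distortion,
scanner-sound interactions, Rician floor effects at very low SNR, and
vertex-accurate cortical geometry.  Passing tests therefore show that the
algorithms behave as specified on data with the assumed statistical
structure, not that real acquisitions meet those assumptions.

## Problem sizes used in the test suite

Unit tests run on short reduced designs (120 volumes, 10 trials in the
same 5–7 volume interval structure) and grids of 8³–16³ voxels.  The
directional cohort uses 20 subjects × 2 runs on a 16×12×12 grid at the
full 230-volume design, chosen so that the dominant signal components sit
just above the thermal singular-value edge — the partial-retention regime
where denoising visibly trades bias for variance.  At this scale the
across-trial t gain, beta shrinkage (larger under the aggressive
threshold), removed-design-variance ordering, tSNR dependence of the beta
change, and laminar slope flattening all reproduce directionally; the
beta-map reliability gain is carried by the conservative threshold, with
the aggressive variant roughly neutral — the same asymmetry the group
statistics show on real data.  The low-tSNR (~20) recovery scenario
raises the structured physiological amplitude over the thermal level,
reflecting that thermal-targeted denoising operates alongside structured
noise it does not remove.

## Known limitations

- Magnitude-only mode approximates Rician noise as Gaussian.
- The g-factor map and σ̂ are estimated, not known; the noise-scan
  calibration absorbs average error, but voxelwise mis-normalization of a
  few percent remains and slightly blurs the threshold.
- Overlap averaging is unweighted; no sliding-window aggregation weights.
- Exhaustive sign-flip tests are limited to n ≤ 20 subjects.
- The pipeline is single-threaded; denoising cost is dominated by one SVD
  per patch.
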