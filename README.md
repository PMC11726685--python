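# nordiceval

Locally low-rank thermal-noise denoising for fMRI (NORDIC-style), together
with the complete evaluation methodology needed to judge what such
denoising does to event-related data: single-trial GLM estimation,
split-half/run-to-run reliability, variance partitioning of removed versus
retained signal, and laminar/tonotopic profiling — all driven by a
synthetic complex-valued fMRI generator with known ground truth, so every
stage is verifiable without downloading any data.

## Who this is for

Submillimeter fMRI lives in a thermal-noise-dominated regime: the dominant
noise is zero-mean Gaussian in the complex MR signal, spatially amplified
by parallel-imaging reconstruction (the g-factor map *g(v)*).  Patch-based
PCA denoising removes principal components that are indistinguishable from
that noise, which raises detection sensitivity — but may also remove weak
task signal.  This package is for researchers who want to apply such
denoising to low-SNR event-related data (the motivating case is slow
event-related auditory stimulation at 7 T) and, crucially, to *quantify
the bias-variance tradeoff* it introduces, on data where the truth is
known.

## The method

**Denoising.**  For a 4D complex series (magnitude + phase NIfTI):

1. remove a volume-specific low-spatial-frequency phase estimate
   (Tukey-windowed k-space low-pass, scale factor 10);
2. normalize by the estimated g-factor map so thermal noise is i.i.d.
   across voxels;
3. slide cubic patches over the volume (patch voxels ≈ 11 × timepoints)
   and form each patch's Casorati matrix **Y** (voxels × time);
4. hard-threshold the singular values of **Y** at a cutoff obtained by
   Monte-Carlo simulation of pure-noise matrices — the mean largest
   singular value of an M×N matrix with i.i.d. N(0, σ²) entries, which for
   large matrices is the Marchenko–Pastur bulk edge σ(√M + √N);
5. average overlapping patch reconstructions and re-apply the g-factor.

Two threshold modes reproduce the two processing strategies evaluated
against the original data:

- `noise_scan` — σ is calibrated from appended no-excitation noise
  volumes (aggressive, the default-settings strategy);
- `gfactor_only` — no noise scan; the cutoff is scaled by 1/√2
  (conservative: fewer components removed).

**Evaluation.**  Per run: temporal filtering (Fourier high-pass at 7
cycles/run, temporal Gaussian FWHM 2 volumes), percent-signal-change
normalization, and an OLS GLM with one predictor per trial (36 trials +
constant; two-gamma HRF peaking at 5 s, kernel summing to 1, so betas are
in PSC units).  Statistics use the *across-trial* variability:
t = mean(β)/(sd(β)/√n).  Reliability is Pearson correlation of beta/t maps
across random split-halves of the runs (50 repetitions, Fisher-z
aggregated), run pairs, and leave-one-run-out folds.  Variance
partitioning regresses the original series on the denoised one,
y_ori = α·y_AN + b + ε, which splits the total sum of squares exactly into
a retained part (α²·SS(y_AN)) and a removed part (SS(ε)); regressing each
piece on the design matrix then quantifies how much task-related variance
denoising removed.  Group inference uses repeated-measures ANOVA with
Greenhouse–Geisser correction and exhaustive 2^n sign-flip permutation
tests with Bonferroni correction.

**Simulator.**  Generates complex runs S(v,t) = baseline·(1 + PSC/100 +
physio/100)·e^{iφ} + g(v)·σ·(ξ₁+iξ₂) with a randomized six-condition
tone-sequence design (10/10/4/4/4/4 trials, inter-trial intervals of 5–7
volumes averaging exactly 6), plus appended noise-only scans.  Ground
truth (per-condition response maps, g-factor, cortical-depth labels 1–11,
ROI labels) is retained for validation.

## Worked example

Simulate one subject (two runs, 16×12×12 voxels, 230 volumes + 5 noise
scans) and compare the three processing strategies inside the active ROI:

```python
import numpy as np
from nordiceval import (SimConfig, StudyConfig, simulate_subject,
                        analyze_subject, spatial_correlation)

study = StudyConfig(sim=SimConfig(grid_shape=(16, 12, 12), seed=1), n_runs=2)
subject = simulate_subject(study.sim, study.n_runs, subject_id=0)
analysis = analyze_subject(subject, study)
roi = subject.truth.roi_labels > 0
for strategy in ("original", "noise_scan", "gfactor_only"):
    runs = analysis.by_strategy[strategy]
    med_t = np.median([np.nanmedian(sr.tmap.t[roi]) for sr in runs])
    beta = np.mean([sr.betas.betas[roi].mean() for sr in runs])
    maps = [m[roi] for m in analysis.mean_beta_maps(strategy, "PredH")]
    print(strategy, round(med_t, 2), round(beta, 3),
          round(spatial_correlation(maps[0], maps[1]), 3))
```

prints

```
strategy        median t  mean beta (%)  run-to-run r
original            2.33          1.826         0.328
noise_scan          7.24          1.536         0.228
gfactor_only        2.75          1.788         0.318
```

Read: the aggressive noise-scan threshold trebles the median across-trial
t statistic (variance across trials collapses) but shrinks the mean
response estimate from 1.83 % to 1.54 % PSC — part of the weak task signal
is removed along with the noise.  The conservative 1/√2 variant gains less
sensitivity but barely biases the betas.  This single subject sits at the
desk-scale operating point; cohort-level directional behaviour (20
simulated subjects) is exercised in `tests/test_acceptance.py`.

The same pipeline is scriptable from the shell:

```bash
nordiceval run-all --out results/demo --subjects 1 --runs 2 --seed 1
nordiceval simulate --out sim/ --runs 2 --seed 7
nordiceval denoise --mag sim/run-00_mag.nii --phase sim/run-00_phase.nii \
    --mode noise_scan --noise-vols 5 --out den/
```

`run-all` writes per-strategy beta/t maps (NIfTI), tidy `metrics.csv`,
laminar profiles, tSNR-binned beta differences and a provenance manifest.

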