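"""Single-trial GLM analysis of event-related fMRI time series.

The analysis chain implemented here follows common practice for slow
event-related designs at high field: the time series is temporally filtered
(Fourier high-pass plus a mild temporal Gaussian), normalized to percent
signal change (PSC), and fitted with an ordinary-least-squares GLM in which
every trial has its own predictor (an HRF-shaped regressor placed at the
trial onset) plus a constant.  Because the HRF kernel sums to one and each
column is a shifted copy of it, the fitted single-trial beta weights are in
PSC units.  Statistical maps are then built from the *across-trial*
variability of the betas (a one-sample t over trials), not from the GLM
residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignMatrix",
    "BetaMaps",
    "TMap",
    "two_gamma_hrf",
    "build_design",
    "temporal_filter",
    "psc_normalize",
    "fit_glm",
    "trial_t",
    "tsnr",
    "fdr_mask",
]

#: conversion between a Gaussian FWHM and its standard deviation
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def two_gamma_hrf(
    dt: float,
    peak: float = 5.0,
    undershoot_peak: float = 15.0,
    undershoot_ratio: float = 6.0,
    duration: float = 30.0,
) -> np.ndarray:
    """Canonical two-gamma hemodynamic response function.

    Difference of two gamma densities (unit scale): the positive lobe peaks
    at ``peak`` seconds after stimulus onset, the undershoot peaks around
    ``undershoot_peak`` seconds with relative amplitude ``1/undershoot_ratio``.
    The kernel is sampled every ``dt`` seconds over ``duration`` seconds and
    normalized so that its entries sum to one; with a design matrix whose
    columns are shifted copies of this kernel, GLM betas are directly in
    percent-signal-change units.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    # gamma density with unit scale has its mode at (shape - 1)
    h = stats.gamma.pdf(t, peak + 1.0) - stats.gamma.pdf(t, undershoot_peak + 1.0) / undershoot_ratio
    return h / h.sum()


@dataclass
class DesignMatrix:
    """HRF-convolved single-trial design: T × (n_trials + 1) with a constant."""

    X: np.ndarray
    hrf_kernel: np.ndarray
    column_labels: list[str]
    condition_of_trial: list[str]
    tr_seconds: float

    @property
    def n_trials(self) -> int:
        return self.X.shape[1] - 1

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]


def build_design(design, n_volumes: int) -> DesignMatrix:
    """Build the single-trial design matrix for an event design.

    ``design`` needs ``trials`` (a sequence of ``(condition, onset_volume)``
    pairs) and ``tr_seconds``.  Each trial contributes one column: the HRF
    sampled at the TR, shifted to the trial's onset volume.  The last column
    is the constant.
    """
    hrf = two_gamma_hrf(design.tr_seconds)
    trials = list(design.trials)
    X = np.zeros((n_volumes, len(trials) + 1))
    labels: list[str] = []
    conditions: list[str] = []
    for k, (condition, onset) in enumerate(trials):
        onset = int(onset)
        if not 0 <= onset < n_volumes:
            raise ValueError(
                f"trial {k} ({condition}) onset {onset} outside run of {n_volumes} volumes"
            )
        seg = hrf[: n_volumes - onset]
        X[onset : onset + seg.size, k] = seg
        labels.append(f"{condition}_{k:02d}")
        conditions.append(condition)
    X[:, -1] = 1.0
    labels.append("constant")
    return DesignMatrix(X=X, hrf_kernel=hrf, column_labels=labels,
                        condition_of_trial=conditions, tr_seconds=design.tr_seconds)


def temporal_filter(
    data: np.ndarray,
    highpass_cycles: int = 7,
    smooth_fwhm_points: float = 2.0,
    axis: int = -1,
) -> np.ndarray:
    """High-pass then temporally smooth a time series along ``axis``.

    The high-pass removes Fourier components at 1 .. ``highpass_cycles``-1
    cycles per run while retaining the mean (cycle 0); smoothing is a
    temporal Gaussian of the given FWHM in samples.  Both steps are linear
    and the order is fixed (high-pass, then smooth).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[axis]
    spec = np.fft.rfft(data, axis=axis)
    cut = min(int(highpass_cycles), spec.shape[axis])
    sl = [slice(None)] * spec.ndim
    sl[axis] = slice(1, cut)
    spec[tuple(sl)] = 0.0
    out = np.fft.irfft(spec, n=n, axis=axis)
    if smooth_fwhm_points and smooth_fwhm_points > 0:
        out = ndimage.gaussian_filter1d(
            out, sigma=smooth_fwhm_points * _FWHM_TO_SIGMA, axis=axis, mode="nearest"
        )
    return out


def psc_normalize(data: np.ndarray, axis: int = -1, eps: float = 1e-12):
    """Normalize a time series to percent signal change about its mean.

    Returns ``(psc, valid)`` where ``psc = 100 * (y - mean) / mean`` and
    ``valid`` marks voxels whose temporal mean is usably far from zero;
    invalid voxels are returned as all-zero and should be excluded from any
    analysis mask.
    """
    data = np.asarray(data, dtype=float)
    mean = data.mean(axis=axis, keepdims=True)
    valid = np.abs(mean) > eps
    safe = np.where(valid, mean, 1.0)
    psc = 100.0 * (data - mean) / safe
    psc = np.where(valid, psc, 0.0)
    return psc, np.squeeze(valid, axis=axis)


@dataclass
class BetaMaps:
    """Per-voxel single-trial response estimates (percent-signal units)."""

    betas: np.ndarray  # (..., n_trials)
    condition_of_trial: list[str]
    constant: np.ndarray  # (...,) fitted intercept
    run_id: int | None = None

    def condition_mean(self, condition: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.condition_of_trial) if c == condition]
        if not idx:
            raise KeyError(f"no trials of condition {condition!r}")
        return self.betas[..., idx].mean(axis=-1)

    def trial_indices(self, contrast: str) -> list[int]:
        if contrast == "all_sounds":
            return list(range(len(self.condition_of_trial)))
        idx = [i for i, c in enumerate(self.condition_of_trial) if c == contrast]
        if not idx:
            raise KeyError(f"no trials of condition {contrast!r}")
        return idx


def _collinear_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    """Name the columns involved in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag <= tol)]
    return [labels[i] for i in sorted(bad)]


def fit_glm(Y: np.ndarray, design: DesignMatrix, run_id: int | None = None) -> BetaMaps:
    """Ordinary-least-squares single-trial GLM.

    ``Y`` has time on the last axis (any leading voxel shape).  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    X = design.X
    T, K = X.shape
    Y = np.asarray(Y, dtype=float)
    if Y.shape[-1] != T:
        raise ValueError(f"time axis mismatch: data has {Y.shape[-1]} volumes, design {T}")
    if T <= K:
        raise ValueError(f"need more volumes ({T}) than design columns ({K})")
    if np.linalg.matrix_rank(X) < K:
        bad = _collinear_columns(X, design.column_labels)
        raise np.linalg.LinAlgError(f"design matrix is rank deficient; collinear columns: {bad}")
    vshape = Y.shape[:-1]
    coefs, *_ = np.linalg.lstsq(X, Y.reshape(-1, T).T, rcond=None)
    coefs = coefs.T.reshape(vshape + (K,))
    return BetaMaps(
        betas=coefs[..., :-1],
        condition_of_trial=list(design.condition_of_trial),
        constant=coefs[..., -1],
        run_id=run_id,
    )


@dataclass
class TMap:
    """Across-trial one-sample t map: mean over trial betas / SE over trials."""

    t: np.ndarray
    dof: int
    contrast: str

    def p_values(self, two_sided: bool = True) -> np.ndarray:
        p = stats.t.sf(np.abs(self.t), self.dof)
        return 2.0 * p if two_sided else p


def trial_t(betas: BetaMaps, contrast: str = "all_sounds") -> TMap:
    """t statistic of the single-trial betas against zero.

    Uses the across-trial variability (t = mean / (sd / sqrt(n)), dof = n-1),
    not the GLM residual variance.  Voxels with zero across-trial variance
    are undefined and returned as NaN.
    """
    idx = betas.trial_indices(contrast)
    if len(idx) < 2:
        raise ValueError(f"contrast {contrast!r} has fewer than 2 trials")
    vals = betas.betas[..., idx]
    n = vals.shape[-1]
    mean = vals.mean(axis=-1)
    sd = vals.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return TMap(t=t, dof=n - 1, contrast=contrast)


def tsnr(data: np.ndarray, axis: int = -1) -> np.ndarray:
    """Temporal SNR: voxelwise mean / standard deviation of the series.

    Zero-variance voxels are undefined (NaN).  Scale invariant by
    construction.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[axis] < 2:
        raise ValueError("need at least 2 timepoints")
    mean = data.mean(axis=axis)
    sd = data.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, mean / sd, np.nan)


def fdr_mask(tmap: TMap, q: float = 0.01):
    """Benjamini-Hochberg FDR thresholding of a t map.

    Two-sided p-values from the t distribution with the map's dof, BH step-up
    at level ``q``.  Returns ``(mask, p_threshold)`` where ``p_threshold`` is
    the largest rejected p (0.0 if nothing is rejected); NaN voxels are never
    significant.
    """
    t = np.asarray(tmap.t, dtype=float)
    finite = np.isfinite(t)
    if not finite.any():
        raise ValueError("t map contains no defined voxels")
    p = 2.0 * stats.t.sf(np.abs(t[finite]), tmap.dof)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    mask = np.zeros(t.shape, dtype=bool)
    mask[finite] = reject
    p_threshold = float(p[reject].max()) if reject.any() else 0.0
    return mask, p_threshold
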