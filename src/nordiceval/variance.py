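"""Variance partitioning of original vs denoised time series.

Per voxel, the original series is regressed on the denoised series with an
intercept (ordinary least squares, equivalent to Gram-Schmidt
orthogonalization):

    y_ori = alpha * y_an + b + eps

which splits the total sum of squares of the original data (about its mean)
exactly into the part retained by denoising (alpha² × SS of the denoised
series) and the part removed (SS of the residual eps, which is orthogonal
to the denoised series and the constant).  Each of the three signals
(original, denoised, residual) is then regressed on the experimental design
matrix to quantify how much design-related variance each carries; the
design-explained SS of the *residual*, relative to the total original SS,
is the portion of task signal that denoising removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import DesignMatrix

__all__ = [
    "VariancePartition",
    "orthogonalize",
    "ss_decompose",
    "design_explained_ss",
    "partition_voxelwise",
    "removed_signal_fraction",
]

_CONST_TOL = 1e-12


def orthogonalize(y_ori: np.ndarray, y_an: np.ndarray):
    """OLS fit ``y_ori = alpha * y_an + b + eps``; supports voxel batches.

    Inputs have time on the last axis.  Returns ``(alpha, intercept,
    residual)``; the residual is orthogonal to ``y_an`` and to the constant
    at machine precision.  Raises if ``y_an`` is constant (for batched
    input, constant voxels should be masked out beforehand; see
    :func:`partition_voxelwise`).
    """
    y_ori = np.asarray(y_ori, dtype=float)
    y_an = np.asarray(y_an, dtype=float)
    if y_ori.shape != y_an.shape:
        raise ValueError("series must have equal shape")
    if y_ori.shape[-1] < 3:
        raise ValueError("need at least 3 timepoints")
    an_c = y_an - y_an.mean(axis=-1, keepdims=True)
    ss_an = (an_c**2).sum(axis=-1)
    if np.any(ss_an <= _CONST_TOL * y_an.shape[-1]):
        raise ValueError("denoised series is constant; cannot orthogonalize")
    ori_c = y_ori - y_ori.mean(axis=-1, keepdims=True)
    alpha = (ori_c * an_c).sum(axis=-1) / ss_an
    intercept = y_ori.mean(axis=-1) - alpha * y_an.mean(axis=-1)
    residual = y_ori - alpha[..., None] * y_an - intercept[..., None]
    return alpha, intercept, residual


def ss_decompose(y_ori: np.ndarray, alpha: np.ndarray, y_an: np.ndarray,
                 residual: np.ndarray):
    """Sum-of-squares ledger (all about the respective means).

    Returns ``(ss_total_ori, ss_an_scaled, ss_resid)`` satisfying the exact
    OLS identity ``ss_total_ori = ss_an_scaled + ss_resid``.
    """
    y_ori = np.asarray(y_ori, dtype=float)
    y_an = np.asarray(y_an, dtype=float)
    ss_total = ((y_ori - y_ori.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    ss_an = ((y_an - y_an.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    ss_an_scaled = np.asarray(alpha) ** 2 * ss_an
    ss_resid = (np.asarray(residual) ** 2).sum(axis=-1)
    return ss_total, ss_an_scaled, ss_resid


def design_explained_ss(y: np.ndarray, design: DesignMatrix):
    """Design-explained and error SS of an OLS fit of ``y`` on the design.

    ``ss_design`` is the SS of the fitted values about their mean,
    ``ss_error`` the residual SS; with the constant column in the design,
    ``ss_design + ss_error`` equals the SS of ``y`` about its mean.
    """
    X = design.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    y = np.asarray(y, dtype=float)
    flat = y.reshape(-1, y.shape[-1])
    coef, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    fitted = (X @ coef).T
    ss_design = ((fitted - fitted.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    ss_error = ((flat - fitted) ** 2).sum(axis=-1)
    shape = y.shape[:-1]
    return ss_design.reshape(shape), ss_error.reshape(shape)


@dataclass
class VariancePartition:
    """Per-voxel partition of the original series against a denoised one."""

    alpha: np.ndarray
    intercept: np.ndarray
    ss_total_ori: np.ndarray
    ss_an_scaled: np.ndarray
    ss_resid: np.ndarray
    ss_design_ori: np.ndarray
    ss_design_an: np.ndarray
    ss_design_resid: np.ndarray
    valid: np.ndarray          # False where the denoised series was ~constant
    n_excluded: int


def partition_voxelwise(y_ori: np.ndarray, y_an: np.ndarray,
                        design: DesignMatrix) -> VariancePartition:
    """Run the full decomposition for every voxel (time on the last axis).

    Voxels whose denoised series is near-constant cannot be orthogonalized;
    they are excluded (``valid=False``, NaN outputs) and counted.
    """
    y_ori = np.asarray(y_ori, dtype=float)
    y_an = np.asarray(y_an, dtype=float)
    an_c = y_an - y_an.mean(axis=-1, keepdims=True)
    ss_an = (an_c**2).sum(axis=-1)
    valid = ss_an > _CONST_TOL * y_an.shape[-1]
    n_excluded = int((~valid).sum())

    safe_an = np.where(valid[..., None], y_an, np.arange(y_an.shape[-1], dtype=float))
    alpha, intercept, residual = orthogonalize(y_ori, safe_an)
    ss_total, ss_an_scaled, ss_resid = ss_decompose(y_ori, alpha, safe_an, residual)
    ss_design_ori, _ = design_explained_ss(y_ori, design)
    ss_design_an, _ = design_explained_ss(y_an, design)
    ss_design_resid, _ = design_explained_ss(residual, design)

    def _mask(a):
        a = np.asarray(a, dtype=float).copy()
        a[~valid] = np.nan
        return a

    return VariancePartition(
        alpha=_mask(alpha), intercept=_mask(intercept),
        ss_total_ori=_mask(ss_total), ss_an_scaled=_mask(ss_an_scaled),
        ss_resid=_mask(ss_resid), ss_design_ori=_mask(ss_design_ori),
        ss_design_an=_mask(ss_design_an), ss_design_resid=_mask(ss_design_resid),
        valid=valid, n_excluded=n_excluded,
    )


def removed_signal_fraction(partition: VariancePartition) -> np.ndarray:
    """Design-explained SS in the removed component, relative to total SS.

    The fraction of the original variance that is both related to the
    design and absent from the denoised data — i.e., task signal removed by
    denoising.  Undefined (NaN) where the total SS is zero.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(partition.ss_total_ori > 0,
                        partition.ss_design_resid / partition.ss_total_ori, np.nan)
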