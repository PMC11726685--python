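"""Cortical-depth profiles and best-frequency (tonotopic) maps.

Depth sampling is volumetric: integer depth labels 1..11 (deep to
superficial) are supplied per voxel, standing in for equivolume surface
sampling.  A laminar profile averages single-trial betas over the voxels of
each depth first, then takes the mean and the across-trial variability of
the resulting trial values.  Best-frequency maps label each significant
voxel by the condition (high or low target frequency) evoking the larger
response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import BetaMaps

__all__ = [
    "DepthProfile",
    "BestFrequencyMap",
    "LABEL_OUTSIDE",
    "LABEL_LOW",
    "LABEL_HIGH",
    "LABEL_UNTUNED",
    "laminar_profile",
    "best_frequency",
]

N_DEPTHS = 11

LABEL_OUTSIDE = 0
LABEL_LOW = 1
LABEL_HIGH = 2
LABEL_UNTUNED = 3


@dataclass
class DepthProfile:
    """Mean response and across-trial variability per cortical depth."""

    depths: np.ndarray            # 1..11
    mean_beta: np.ndarray         # per depth
    trial_variability: np.ndarray  # sd across trials, per depth
    condition: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth": self.depths,
            "mean_beta": self.mean_beta,
            "trial_sd": self.trial_variability,
            "condition": self.condition,
        })

    def slope(self) -> float:
        """Least-squares slope of mean beta over depth index (draining-vein
        gradients make this positive toward the surface in GE-BOLD)."""
        return float(np.polyfit(self.depths, self.mean_beta, 1)[0])


def laminar_profile(betas: BetaMaps, depth_labels: np.ndarray, roi: np.ndarray,
                    condition: str = "all_sounds") -> DepthProfile:
    """Depth-dependent response profile within an ROI.

    Per depth (1..11): average the single-trial betas over the ROI voxels of
    that depth, then take mean and sd across trials.  Raises, naming the
    bins, if any depth has no voxel in the ROI.
    """
    depth_labels = np.asarray(depth_labels)
    roi = np.asarray(roi, dtype=bool)
    if depth_labels.shape != roi.shape or depth_labels.shape != betas.betas.shape[:-1]:
        raise ValueError("depth labels, ROI and beta maps must share the voxel grid")
    idx = betas.trial_indices(condition)
    trial_betas = betas.betas[..., idx]

    empty = [d for d in range(1, N_DEPTHS + 1) if not np.any(roi & (depth_labels == d))]
    if empty:
        raise ValueError(f"empty depth bins in ROI: {empty}")

    depths = np.arange(1, N_DEPTHS + 1)
    mean_beta = np.empty(N_DEPTHS)
    trial_sd = np.empty(N_DEPTHS)
    for i, d in enumerate(depths):
        sel = roi & (depth_labels == d)
        per_trial = trial_betas[sel].mean(axis=0)  # average voxels, keep trials
        mean_beta[i] = per_trial.mean()
        trial_sd[i] = per_trial.std(ddof=1) if per_trial.size > 1 else 0.0
    return DepthProfile(depths=depths, mean_beta=mean_beta,
                        trial_variability=trial_sd, condition=condition)


@dataclass
class BestFrequencyMap:
    """Per-voxel frequency-preference labels inside a significance mask."""

    labels: np.ndarray  # LABEL_* codes
    condition_pair: tuple[str, str]

    def accuracy(self, true_prefers_high: np.ndarray,
                 mask: np.ndarray | None = None) -> float:
        """Fraction of labelled (non-untuned) voxels matching a truth map."""
        tuned = (self.labels == LABEL_LOW) | (self.labels == LABEL_HIGH)
        if mask is not None:
            tuned &= np.asarray(mask, dtype=bool)
        if not tuned.any():
            return float("nan")
        predicted_high = self.labels[tuned] == LABEL_HIGH
        return float((predicted_high == np.asarray(true_prefers_high)[tuned]).mean())


def best_frequency(beta_high: np.ndarray, beta_low: np.ndarray,
                   tmask: np.ndarray, tie_tol: float = 1e-9,
                   condition_pair: tuple[str, str] = ("PredH", "PredL")) -> BestFrequencyMap:
    """Best-frequency map from two condition beta maps.

    Within the significance mask, each voxel is labelled by the condition
    with the larger beta; differences below ``tie_tol`` are untuned.
    """
    beta_high = np.asarray(beta_high, dtype=float)
    beta_low = np.asarray(beta_low, dtype=float)
    tmask = np.asarray(tmask, dtype=bool)
    if beta_high.shape != beta_low.shape or beta_high.shape != tmask.shape:
        raise ValueError("maps and mask must share the voxel grid")
    labels = np.full(beta_high.shape, LABEL_OUTSIDE, dtype=np.int8)
    diff = beta_high - beta_low
    labels[tmask & (diff > tie_tol)] = LABEL_HIGH
    labels[tmask & (diff < -tie_tol)] = LABEL_LOW
    labels[tmask & (np.abs(diff) <= tie_tol)] = LABEL_UNTUNED
    return BestFrequencyMap(labels=labels, condition_pair=condition_pair)
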