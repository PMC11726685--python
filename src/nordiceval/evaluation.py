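"""Reliability, similarity and group-level inference machinery.

Covers the evaluation side of the denoising comparison: voxelwise spatial
correlations of beta/t maps, repeated split-half reliability across runs,
leave-one-run-out (LORO) cross-validation against the original data's
average map, Fisher-z aggregation of correlations, exhaustive sign-flip
permutation tests, repeated-measures ANOVA with Greenhouse-Geisser
correction, Bonferroni adjustment, and the tSNR-binned beta-change summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplitScheme",
    "ReliabilityResult",
    "spatial_correlation",
    "split_half_reliability",
    "loro_correlation",
    "fisher_z",
    "inverse_fisher_z",
    "fisher_z_mean",
    "sign_flip_permutation_test",
    "rm_anova",
    "gg_epsilon",
    "beta_tsnr_bins",
    "bonferroni",
]

_R_CLIP = 1.0 - 1e-12


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two voxel maps over a mask.

    Returns NaN if either map has zero variance in the mask.
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have equal size")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        a, b = a[m], b[m]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 voxels")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def fisher_z(r: float) -> float:
    """Fisher z transform, z = atanh(r); defined for |r| < 1."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return float(np.arctanh(r))


def inverse_fisher_z(z: float) -> float:
    return float(np.tanh(z))


def fisher_z_mean(rs) -> float:
    """Fisher-z mean of correlations; r is clipped to 1 - 1e-12 first."""
    rs = np.clip(np.asarray(rs, dtype=float), -_R_CLIP, _R_CLIP)
    return float(np.arctanh(rs).mean())


@dataclass
class SplitScheme:
    """Repeated random split-half scheme over runs."""

    n_repetitions: int = 50
    seed: int = 0

    def splits(self, n_runs: int):
        if n_runs < 2:
            raise ValueError("need at least 2 runs to split")
        rng = np.random.default_rng([int(self.seed) % (2**31), 6])
        for _ in range(self.n_repetitions):
            perm = rng.permutation(n_runs)
            half = n_runs // 2
            yield np.sort(perm[:half]), np.sort(perm[half:])


@dataclass
class ReliabilityResult:
    """Split-half correlations and their Fisher-z aggregate."""

    r_values: np.ndarray
    z_mean: float

    @property
    def r_mean(self) -> float:
        return float(np.tanh(self.z_mean))


def split_half_reliability(run_maps, scheme: SplitScheme | None = None,
                           mask: np.ndarray | None = None) -> ReliabilityResult:
    """Spatial replicability of per-run maps under repeated split-half.

    ``run_maps`` is a sequence of per-run voxel maps (e.g., mean-beta maps).
    For each repetition the runs are partitioned into two halves (sizes
    differing by at most one), maps are averaged within each half, and the
    halves are correlated within the mask; the 50 (by default) correlations
    are aggregated as a Fisher-z mean.
    """
    maps = np.asarray([np.asarray(m, dtype=float).ravel() for m in run_maps])
    n_runs = maps.shape[0]
    if n_runs < 2:
        raise ValueError("split-half reliability needs at least 2 runs")
    scheme = scheme or SplitScheme()
    rs = []
    for half_a, half_b in scheme.splits(n_runs):
        rs.append(spatial_correlation(maps[half_a].mean(axis=0),
                                      maps[half_b].mean(axis=0), mask=mask))
    rs = np.asarray(rs)
    return ReliabilityResult(r_values=rs, z_mean=fisher_z_mean(rs))


def loro_correlation(original_run_maps, strategy_run_maps,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-run-out correlation against the original data's average.

    The reference map for fold ``i`` is the average of all *original* runs
    except ``i``; it is correlated with the left-out run's map from the
    strategy under evaluation.  Returns one correlation per run.
    """
    ref_maps = np.asarray([np.asarray(m, dtype=float).ravel() for m in original_run_maps])
    strat_maps = np.asarray([np.asarray(m, dtype=float).ravel() for m in strategy_run_maps])
    n_runs = ref_maps.shape[0]
    if n_runs < 3:
        raise ValueError("LORO needs at least 3 runs")
    if strat_maps.shape != ref_maps.shape:
        raise ValueError("strategy maps must match original maps in number and size")
    out = np.empty(n_runs)
    for i in range(n_runs):
        others = np.delete(np.arange(n_runs), i)
        reference = ref_maps[others].mean(axis=0)
        out[i] = spatial_correlation(strat_maps[i], reference, mask=mask)
    return out


def sign_flip_permutation_test(paired_diffs) -> float:
    """Exhaustive two-sided sign-flip permutation test on paired differences.

    Enumerates all 2^n sign assignments of the per-subject differences;
    p is the proportion of assignments whose |mean| is at least the observed
    |mean|.  The p-value has resolution exactly 1/2^n and always includes
    the identity assignment (p > 0).
    """
    d = np.asarray(paired_diffs, dtype=float)
    n = d.size
    if n == 0:
        raise ValueError("no paired differences")
    if n > 20:
        raise ValueError("exhaustive enumeration supported up to n = 20")
    obs = abs(d.mean())
    total = 1 << n
    count = 0
    chunk = 1 << 16
    shifts = np.arange(n, dtype=np.uint32)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.uint32)
        bits = (idx[:, None] >> shifts) & 1
        signs = 1.0 - 2.0 * bits
        means = np.abs(signs @ d) / n
        count += int(np.count_nonzero(means >= obs - 1e-12))
    return count / total


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str) -> pd.DataFrame:
    """Repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``within`` is one factor name or a list of two (processing strategy,
    optionally crossed with condition).  Returns the ANOVA table (one row
    per effect) with columns ``F``, ``p_unc``, ``eps`` and ``p_GG_corr``;
    with two factors the table includes both main effects and the
    interaction.  Requires a complete subject × cell table.
    """
    import pingouin as pg

    if isinstance(within, str):
        within = [within]
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within factors are supported")
    wide = data.pivot_table(index=subject, columns=list(within), values=dv)
    if wide.isna().any().any():
        raise ValueError("missing cells in the subject × condition table")
    table = pg.rm_anova(data=data, dv=dv, within=within if len(within) > 1 else within[0],
                        subject=subject, correction=True, detailed=True)
    if "p_GG_corr" not in table.columns:  # pingouin omits it for 2-level one-way
        table["eps"] = table.get("eps", 1.0)
        table["p_GG_corr"] = table["p_unc"]
    return table


def beta_tsnr_bins(beta_diff: np.ndarray, tsnr: np.ndarray, n_bins: int = 10,
                   scheme: str = "equal_count") -> pd.DataFrame:
    """Mean beta change per tSNR bin.

    Bins the voxels by tSNR (equal-count quantile bins by default, or
    ``scheme='equal_width'``) and returns a table with the bin edges, voxel
    count and mean of ``beta_diff`` per bin; empty bins are reported with
    NaN means, never as zero.
    """
    bd = np.asarray(beta_diff, dtype=float).ravel()
    ts = np.asarray(tsnr, dtype=float).ravel()
    if bd.shape != ts.shape:
        raise ValueError("beta_diff and tsnr must match in size")
    ok = np.isfinite(bd) & np.isfinite(ts)
    bd, ts = bd[ok], ts[ok]
    if scheme == "equal_count":
        edges = np.unique(np.quantile(ts, np.linspace(0, 1, n_bins + 1)))
    elif scheme == "equal_width":
        edges = np.linspace(ts.min(), ts.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    idx = np.clip(np.searchsorted(edges, ts, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for i in range(len(edges) - 1):
        in_bin = idx == i
        rows.append({
            "bin": i,
            "tsnr_low": edges[i],
            "tsnr_high": edges[i + 1],
            "n_voxels": int(in_bin.sum()),
            "mean_beta_diff": float(bd[in_bin].mean()) if in_bin.any() else np.nan,
            "mean_tsnr": float(ts[in_bin].mean()) if in_bin.any() else np.nan,
        })
    return pd.DataFrame(rows)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    out = np.minimum(1.0, p * m)
    return float(out) if np.isscalar(p_values) or p.ndim == 0 else out
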