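"""Reliability metrics, permutation inference and group-level machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nordiceval import (SplitScheme, beta_tsnr_bins, bonferroni, fisher_z,
                        fisher_z_mean, inverse_fisher_z, loro_correlation,
                        rm_anova, sign_flip_permutation_test,
                        spatial_correlation, split_half_reliability)


class TestSpatialCorrelation:
    def test_identity(self, rng):
        m = rng.standard_normal(100)
        assert spatial_correlation(m, m) == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        m = rng.standard_normal(100)
        assert spatial_correlation(m, -m) == pytest.approx(-1.0)

    def test_independent_maps_near_zero(self, rng):
        a, b = rng.standard_normal((2, 10_000))
        assert abs(spatial_correlation(a, b)) < 0.05

    def test_zero_variance_undefined(self):
        assert np.isnan(spatial_correlation(np.ones(10), np.arange(10.0)))

    def test_mask_applied(self, rng):
        a = rng.standard_normal(50)
        b = a.copy()
        b[25:] = rng.standard_normal(25)
        mask = np.arange(50) < 25
        assert spatial_correlation(a, b, mask=mask) == pytest.approx(1.0)

    def test_too_few_voxels(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(2), np.ones(2))


class TestSplitHalf:
    def test_identical_runs_give_unit_correlation(self, rng):
        m = rng.standard_normal(200)
        res = split_half_reliability([m] * 4, SplitScheme(n_repetitions=10, seed=1))
        np.testing.assert_allclose(res.r_values, 1.0)
        assert res.r_mean == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_runs_near_zero(self, rng):
        runs = rng.standard_normal((6, 5000))
        res = split_half_reliability(runs, SplitScheme(n_repetitions=50, seed=2))
        se = res.r_values.std(ddof=1) / np.sqrt(res.r_values.size)
        assert abs(res.z_mean) < 3 * max(se, 1 / np.sqrt(5000))

    def test_deterministic_split_sequence(self, rng):
        runs = rng.standard_normal((5, 100))
        a = split_half_reliability(runs, SplitScheme(n_repetitions=20, seed=9))
        b = split_half_reliability(runs, SplitScheme(n_repetitions=20, seed=9))
        np.testing.assert_array_equal(a.r_values, b.r_values)

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValueError):
            split_half_reliability([rng.standard_normal(10)])


class TestLoro:
    def test_identical_runs(self, rng):
        m = rng.standard_normal(100)
        rs = loro_correlation([m] * 4, [m] * 4)
        np.testing.assert_allclose(rs, 1.0)
        assert rs.size == 4

    def test_noise_run_uncorrelated(self, rng):
        m = rng.standard_normal(5000)
        strategy = [m, m, rng.standard_normal(5000)]
        rs = loro_correlation([m, m, m], strategy)
        assert abs(rs[2]) < 0.05

    def test_needs_three_runs(self, rng):
        runs = rng.standard_normal((2, 50))
        with pytest.raises(ValueError):
            loro_correlation(runs, runs)


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_half(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), rel=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=50, derandomize=True)
    def test_inverse_roundtrip(self, r):
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_mean_clips_perfect_correlations(self):
        z = fisher_z_mean([1.0, 1.0])
        assert np.isfinite(z)
        assert inverse_fisher_z(z) == pytest.approx(1.0, abs=1e-9)


class TestSignFlip:
    def test_all_positive_ten_subjects(self):
        # only the two all-same-sign assignments reach |mean| = 1
        p = sign_flip_permutation_test(np.ones(10))
        assert p == 2 / 1024

    def test_symmetric_differences_give_p_one(self):
        assert sign_flip_permutation_test([0.5, -0.5, 1.5, -1.5]) == 1.0

    def test_order_invariance(self, rng):
        d = rng.standard_normal(8)
        assert sign_flip_permutation_test(d) == sign_flip_permutation_test(d[::-1])

    def test_resolution_and_range(self, rng):
        d = rng.standard_normal(6)
        p = sign_flip_permutation_test(d)
        assert 0 < p <= 1
        assert (p * 2**6) == pytest.approx(round(p * 2**6))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sign_flip_permutation_test([])


def _long_table(values, subjects=None):
    values = np.asarray(values)
    n, k = values.shape
    return pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "strategy": np.tile([f"s{j}" for j in range(k)], n),
        "value": values.ravel(),
    })


class TestRmAnova:
    def test_two_level_equals_paired_t_squared(self, rng):
        vals = rng.standard_normal((12, 2)) + [0.0, 0.4]
        table = rm_anova(_long_table(vals), dv="value", within="strategy",
                         subject="subject")
        t_stat, p = stats.ttest_rel(vals[:, 0], vals[:, 1])
        row = table.iloc[0]
        assert row["F"] == pytest.approx(t_stat**2, rel=1e-8)
        assert row["p_unc"] == pytest.approx(p, rel=1e-8)
        assert row["eps"] == pytest.approx(1.0)
        assert row["p_GG_corr"] == pytest.approx(p, rel=1e-8)

    def test_location_invariance(self, rng):
        vals = rng.standard_normal((10, 3))
        f1 = rm_anova(_long_table(vals), "value", "strategy", "subject").iloc[0]["F"]
        f2 = rm_anova(_long_table(vals + 100.0), "value", "strategy", "subject").iloc[0]["F"]
        assert f2 == pytest.approx(f1, rel=1e-8)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        n_sims, alpha, rejections = 400, 0.05, 0
        for _ in range(n_sims):
            vals = rng.standard_normal((8, 3))
            p = rm_anova(_long_table(vals), "value", "strategy", "subject").iloc[0]["p_GG_corr"]
            rejections += p < alpha
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) < 4 * se

    def test_two_way_table_has_interaction_with_gg(self, rng):
        n, ka, kb = 10, 3, 2
        rows = []
        vals = rng.standard_normal((n, ka, kb))
        for s in range(n):
            for a in range(ka):
                for b in range(kb):
                    rows.append({"subject": s, "strategy": f"a{a}",
                                 "condition": f"b{b}", "value": vals[s, a, b]})
        table = rm_anova(pd.DataFrame(rows), "value", ["strategy", "condition"],
                         "subject")
        sources = set(table["Source"])
        assert {"strategy", "condition", "strategy * condition"} <= sources
        assert table["p_GG_corr"].notna().all()
        eps = table.set_index("Source").loc["strategy", "eps"]
        assert 1 / (ka - 1) <= eps <= 1.0


class TestBetaTsnrBins:
    def test_zero_diff_gives_zero_means(self, rng):
        tsnr = rng.uniform(5, 50, 500)
        table = beta_tsnr_bins(np.zeros(500), tsnr, n_bins=5)
        np.testing.assert_allclose(table["mean_beta_diff"], 0.0)

    def test_monotone_input_gives_increasing_bins(self, rng):
        tsnr = rng.uniform(5, 50, 2000)
        table = beta_tsnr_bins(tsnr, tsnr, n_bins=8)
        diffs = table["mean_beta_diff"].to_numpy()
        assert np.all(np.diff(diffs) > 0)

    def test_empty_bins_reported_as_nan(self):
        tsnr = np.array([1.0, 1.1, 1.2, 9.0])
        table = beta_tsnr_bins(np.ones(4), tsnr, n_bins=4, scheme="equal_width")
        assert table["mean_beta_diff"].isna().sum() >= 1
        assert table.loc[table["n_voxels"] == 0, "mean_beta_diff"].isna().all()


class TestBonferroni:
    def test_simple(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)

    def test_capped_at_one(self):
        assert bonferroni(0.5, 4) == 1.0

    @given(st.floats(min_value=0, max_value=1))
    @settings(max_examples=25, derandomize=True)
    def test_single_test_unchanged(self, p):
        assert bonferroni(p, 1) == p
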