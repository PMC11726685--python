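"""Locally low-rank denoising: g-factor handling, thresholds, patches."""

import numpy as np
import pytest

from nordiceval import (PatchSpec, TimeSeries4D, denoise_patch,
                        estimate_gfactor_map, generate_design,
                        generate_ground_truth, mc_sv_threshold,
                        nordic_denoise, normalize_by_gfactor, phase_stabilize,
                        synthesize_run)
from nordiceval.nordic import GFACTOR_ONLY_SCALE

from conftest import small_config


def _simulate(cfg):
    truth = generate_ground_truth(cfg)
    design = generate_design(cfg)
    return truth, synthesize_run(design, truth, cfg)


class TestGFactorEstimation:
    def test_homogeneous_noise_gives_flat_map(self):
        cfg = small_config(grid_shape=(8, 8, 8), n_volumes=60, n_noise_scans=500,
                           trials_per_condition={"PredH": 2, "PredL": 2},
                           gfactor_range=(1.0, 1.0))
        _, ts = _simulate(cfg)
        g = estimate_gfactor_map(ts)
        assert np.max(np.abs(g - 1)) < 0.10

    def test_ramp_recovered_from_many_noise_scans(self):
        cfg = small_config(grid_shape=(8, 8, 8), n_volumes=60, n_noise_scans=500,
                           trials_per_condition={"PredH": 2, "PredL": 2},
                           gfactor_range=(1.0, 3.0))
        truth, ts = _simulate(cfg)
        g = estimate_gfactor_map(ts)
        ratio = g / truth.gfactor
        assert ratio.min() > 0.9 and ratio.max() < 1.1

    def test_deterministic(self, small_run):
        *_, ts = small_run
        np.testing.assert_array_equal(estimate_gfactor_map(ts), estimate_gfactor_map(ts))

    def test_all_zero_input_rejected(self):
        ts = TimeSeries4D(magnitude=np.zeros((4, 4, 4, 40)), phase=None,
                          tr_seconds=1.6, n_noise_scans_appended=0)
        with pytest.raises(ValueError, match="zero"):
            estimate_gfactor_map(ts)


class TestNormalizeByGFactor:
    def test_unit_map_is_identity(self, small_run):
        *_, ts = small_run
        out = normalize_by_gfactor(ts, np.ones(ts.grid_shape))
        np.testing.assert_array_equal(out.magnitude, ts.magnitude)

    def test_scalar_division(self):
        ts = TimeSeries4D(magnitude=np.full((2, 2, 2, 5), 10.0), phase=None,
                          tr_seconds=1.6)
        out = normalize_by_gfactor(ts, np.full((2, 2, 2), 2.0))
        np.testing.assert_array_equal(out.magnitude, 5.0)

    def test_normalize_then_denormalize_roundtrip(self, small_run, rng):
        *_, ts = small_run
        g = 1.0 + rng.random(ts.grid_shape)
        back = normalize_by_gfactor(normalize_by_gfactor(ts, g), 1.0 / g)
        np.testing.assert_allclose(back.magnitude, ts.magnitude, rtol=1e-12)

    def test_nonpositive_map_rejected(self, small_run):
        *_, ts = small_run
        with pytest.raises(ValueError, match="positive"):
            normalize_by_gfactor(ts, np.zeros(ts.grid_shape))


class TestMCThreshold:
    def test_zero_sigma_gives_zero(self):
        assert mc_sv_threshold(100, 50, 0.0) == 0.0

    def test_matches_marchenko_pastur_edge(self):
        # independent oracle: bulk edge sigma * (sqrt(m) + sqrt(n))
        got = mc_sv_threshold(1000, 100, 1.0, n_mc=20, seed=0)
        expected = np.sqrt(1000) + np.sqrt(100)
        assert abs(got - expected) / expected < 0.02

    def test_exact_scale_equivariance(self):
        base = mc_sv_threshold(200, 50, 1.5, n_mc=5, seed=3)
        assert mc_sv_threshold(200, 50, 3.0, n_mc=5, seed=3) == pytest.approx(2 * base, rel=1e-15)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            mc_sv_threshold(1, 10, 1.0)
        with pytest.raises(ValueError):
            mc_sv_threshold(10, 10, -1.0)


class TestDenoisePatch:
    def test_signal_above_cutoff_untouched(self, rng):
        u = rng.standard_normal((40, 1))
        v = rng.standard_normal((1, 20))
        a = 10.0 * u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        out, rank = denoise_patch(a, sv_cutoff=5.0)
        assert rank == 1
        np.testing.assert_allclose(out, a, atol=1e-10)

    def test_pure_noise_below_cutoff_zeroed(self, rng):
        a = 0.01 * rng.standard_normal((30, 20))
        out, rank = denoise_patch(a, sv_cutoff=10.0)
        assert rank == 0
        np.testing.assert_array_equal(out, 0.0)

    def test_eckart_young_energy_of_discarded_components(self, rng):
        # rank-3 matrix with singular values {20, 8, 3}; cutoff 5 keeps two
        m, n = 30, 20
        q1, _ = np.linalg.qr(rng.standard_normal((m, 3)))
        q2, _ = np.linalg.qr(rng.standard_normal((n, 3)))
        svals = np.array([20.0, 8.0, 3.0])
        a = (q1 * svals) @ q2.T
        out, rank = denoise_patch(a, sv_cutoff=5.0)
        assert rank == 2
        err = np.linalg.norm(a - out, "fro")
        assert err == pytest.approx(3.0, rel=1e-10)

    def test_nonfinite_rejected(self):
        a = np.ones((4, 4))
        a[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            denoise_patch(a, 1.0)


class TestPhaseStabilize:
    def test_constant_phase_removed(self):
        mag = np.full((12, 12, 12, 3), 5.0)
        phase = np.full_like(mag, 0.8)
        ts = TimeSeries4D(magnitude=mag, phase=phase, tr_seconds=1.6)
        out = phase_stabilize(ts)
        assert np.max(np.abs(out.phase)) < 1e-10

    def test_zero_phase_is_identity(self, rng):
        mag = 1.0 + rng.random((10, 10, 10, 3))
        ts = TimeSeries4D(magnitude=mag, phase=np.zeros_like(mag), tr_seconds=1.6)
        out = phase_stabilize(ts)
        np.testing.assert_allclose(out.phase, 0.0, atol=1e-12)
        np.testing.assert_array_equal(out.magnitude, mag)

    def test_magnitude_preserved(self, small_run):
        *_, ts = small_run
        out = phase_stabilize(ts)
        np.testing.assert_allclose(out.magnitude, ts.magnitude, rtol=1e-10)

    def test_requires_phase(self):
        ts = TimeSeries4D(magnitude=np.ones((8, 8, 8, 4)), phase=None, tr_seconds=1.6)
        with pytest.raises(ValueError, match="phase"):
            phase_stabilize(ts)


class TestNordicDenoise:
    def test_zero_cutoff_identity_path(self, small_run):
        # validates patch bookkeeping: recombination must reproduce the input
        *_, ts = small_run
        out, report = nordic_denoise(ts, mode="noise_scan", sv_cutoff=0.0,
                                     phase_stabilization=False)
        np.testing.assert_allclose(out.magnitude, ts.magnitude, rtol=1e-10, atol=1e-12)
        assert report.kept_ranks == [report.min_mn] * report.n_patches

    def test_noiseless_run_passes_through(self):
        cfg = small_config(sigma_thermal=0.0, physio_amplitude=0.0)
        _, ts = _simulate(cfg)
        out, _ = nordic_denoise(ts, mode="noise_scan", phase_stabilization=False)
        rms = np.sqrt(np.mean((out.magnitude - ts.magnitude) ** 2))
        assert rms / np.sqrt(np.mean(ts.magnitude**2)) < 1e-6

    def test_gfactor_only_mode_is_more_conservative(self, small_run):
        *_, ts = small_run
        _, rep_def = nordic_denoise(ts, mode="noise_scan", seed=1)
        _, rep_nn = nordic_denoise(ts, mode="gfactor_only", seed=1)
        assert rep_nn.threshold.sv_cutoff < rep_def.threshold.sv_cutoff
        assert all(k_nn >= k_def for k_nn, k_def
                   in zip(rep_nn.kept_ranks, rep_def.kept_ranks))

    def test_pure_noise_input_mostly_removed(self):
        cfg = small_config(grid_shape=(12, 12, 12), baseline=0.0, psc_amplitude=0.0,
                           physio_amplitude=0.0)
        _, ts = _simulate(cfg)
        out, _ = nordic_denoise(ts, mode="noise_scan", seed=2)
        assert out.magnitude.var() < 0.10 * ts.magnitude.var()

    def test_output_finite_and_denoising_reduces_error_vs_truth(self):
        # low SNR: thermal noise on top of strong structured physio (tSNR ~ 20)
        cfg = small_config(physio_amplitude=6.0, seed=5)
        truth, ts = _simulate(cfg)
        out, _ = nordic_denoise(ts, mode="noise_scan", seed=5)
        assert np.all(np.isfinite(out.magnitude))
        n = ts.n_data_volumes
        clean = truth.signal_clean
        err_before = (ts.magnitude[..., :n] - clean).std(axis=-1)
        err_after = (out.magnitude[..., :n] - clean).std(axis=-1)
        roi = truth.roi_labels > 0
        improved = err_after[roi] < err_before[roi]
        assert improved.mean() >= 0.95

    def test_patch_larger_than_volume_rejected(self, small_run):
        *_, ts = small_run
        with pytest.raises(ValueError, match="kernel"):
            nordic_denoise(ts, PatchSpec(kernel=(32, 32, 32)), mode="noise_scan")

    def test_noise_scan_mode_requires_noise_scans(self):
        cfg = small_config(n_noise_scans=0)
        _, ts = _simulate(cfg)
        with pytest.raises(ValueError, match="noise scan"):
            nordic_denoise(ts, mode="noise_scan")

    def test_no_noise_scan_cutoff_scale_constant(self):
        assert GFACTOR_ONLY_SCALE == pytest.approx(1 / np.sqrt(2), rel=1e-15)
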