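"""Generators: determinism, count-rate bookkeeping, exact noiseless limits."""

import numpy as np
import pytest

from fcskit import (
    ColocGroundTruth,
    FCSSimConfig,
    FRAPGroundTruth,
    generate_model_acf,
    simulate_fcs_traces,
    simulate_frap_curve,
    simulate_stack_pair,
)
from fcskit.models import FCSModelSpec, eval_model
from fcskit.synthetic import LABEL_COLOC, LABEL_GREEN_ONLY

from conftest import CALIB, make_sim_config


class TestTraceSimulator:
    def test_fixed_seed_is_bit_reproducible(self):
        cfg = make_sim_config(7, duration=0.05, n_particles=(10,))
        t1, _ = simulate_fcs_traces(cfg)
        t2, _ = simulate_fcs_traces(cfg)
        assert np.array_equal(t1[0].counts, t2[0].counts)

    def test_zero_brightness_gives_pure_background(self):
        cfg = make_sim_config(3, duration=0.05, brightness=((0.0,),),
                              background=(5000.0,))
        traces, _ = simulate_fcs_traces(cfg)
        lam = 5000.0 * cfg.bin_time
        mean = traces[0].counts.mean()
        se = np.sqrt(lam / cfg.n_bins)
        assert abs(mean - lam) < 4 * se

    def test_count_rate_matches_expected_rate(self, reference_sims):
        """Time-averaged count rate equals the per-bin expected rate within
        3 standard errors (Poisson) over >= 1e5 bins."""
        for sim in reference_sims[:3]:
            trace = sim["trace"]
            expected = sim["truth"]["expected_rate_hz"][0]
            n = trace.counts.size
            se = np.sqrt(expected / trace.bin_time / n) * trace.bin_time  # counts/bin
            rate_se = se / trace.bin_time
            assert abs(trace.mean_rate - expected) < 3 * rate_se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            make_sim_config(0, bin_time=-1e-6)
        with pytest.raises(ValueError):
            make_sim_config(0, duration=0.001)  # < 1e4 bins
        with pytest.raises(ValueError):
            make_sim_config(0, box_side=1.0)  # < 10 omega_xy

    def test_two_channels_share_trajectories(self, two_channel_sim):
        """Counts in the two channels are Poisson draws of the same
        intensity; after rebinning past shot noise they correlate strongly,
        which independent particles would not."""
        g, r = two_channel_sim["traces"]
        k = 500  # rebin 2 µs -> 1 ms so occupancy fluctuations dominate
        n = g.counts.size // k * k
        cg = g.counts[:n].reshape(-1, k).sum(axis=1)
        cr = r.counts[:n].reshape(-1, k).sum(axis=1)
        assert np.corrcoef(cg, cr)[0, 1] > 0.5


class TestModelACFGenerator:
    def test_zero_noise_equals_model_exactly(self):
        spec = FCSModelSpec("3D", 2, True)
        params = {"N": 8.0, "tau_d1": 2e-4, "tau_d2": 1e-2, "F2": 0.4,
                  "F_trip": 0.1, "tau_trip": 5e-6, "G_inf": 1.0}
        lags = np.logspace(-6, 0, 150)
        curve = generate_model_acf(spec, params, lags, 0.0, calibration=CALIB)[0]
        assert np.array_equal(curve.G, eval_model(spec, params, CALIB, lags))

    def test_amplitude_at_small_lag_is_one_over_N(self):
        spec = FCSModelSpec("3D", 1, False)
        params = {"N": 10.0, "tau_d1": 1e-3, "G_inf": 0.0}
        curve = generate_model_acf(spec, params, np.array([1e-9, 1e-8]),
                                   calibration=CALIB)[0]
        assert curve.G[0] == pytest.approx(0.1, rel=1e-5)

    def test_same_seed_identical_replicates(self):
        spec = FCSModelSpec("2D", 1, True)
        params = {"N": 5.0, "tau_d1": 1e-3, "F_trip": 0.1, "tau_trip": 5e-6,
                  "G_inf": 1.0}
        lags = np.logspace(-6, 0, 80)
        a = generate_model_acf(spec, params, lags, 0.05, 2, seed=12)
        b = generate_model_acf(spec, params, lags, 0.05, 2, seed=12)
        assert np.array_equal(a[0].G, b[0].G)
        assert np.array_equal(a[1].G, b[1].G)
        assert not np.array_equal(a[0].G, a[1].G)

    def test_nonpositive_lags_rejected(self):
        spec = FCSModelSpec("2D", 1, False)
        with pytest.raises(ValueError):
            generate_model_acf(spec, {"N": 1, "tau_d1": 1e-3, "G_inf": 0},
                               np.array([0.0, 1e-3]))


class TestFRAPGenerator:
    def test_immobile_pool_stays_at_bleached_level(self):
        truth = FRAPGroundTruth(F_m=0.0, bleach_depth=0.6, noise_sd=0.0)
        sim = simulate_frap_curve(truth)
        post = sim.intensity[sim.n_prebleach:]
        assert np.allclose(post, 0.4)

    def test_long_time_plateau_identity(self):
        """I(t -> inf) = 1 - depth * (1 - F_m), exactly at zero noise."""
        truth = FRAPGroundTruth(tau_fast=10.0, tau_slow=50.0, F_m=0.4,
                                bleach_depth=0.7, duration=50_000.0,
                                frame_interval=50.0, noise_sd=0.0)
        sim = simulate_frap_curve(truth)
        assert sim.intensity[-1] == pytest.approx(1 - 0.7 * 0.6, abs=1e-4)

    def test_prebleach_frames_at_unity(self):
        sim = simulate_frap_curve(FRAPGroundTruth(noise_sd=0.0))
        assert np.allclose(sim.intensity[: sim.n_prebleach], 1.0)
        assert np.all(sim.time[: sim.n_prebleach] < 0)

    def test_seeded_noise_reproducible(self):
        truth = FRAPGroundTruth(noise_sd=0.02, seed=5)
        a = simulate_frap_curve(truth)
        b = simulate_frap_curve(truth)
        assert np.array_equal(a.intensity, b.intensity)

    def test_short_duration_logs_warning(self, caplog):
        truth = FRAPGroundTruth(tau_fast=300.0, tau_slow=3000.0, duration=600.0)
        with caplog.at_level("WARNING"):
            simulate_frap_curve(truth)
        assert "fit may be unstable" in caplog.text

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            FRAPGroundTruth(tau_fast=100.0, tau_slow=50.0)
        with pytest.raises(ValueError):
            FRAPGroundTruth(F_m=1.5)
        with pytest.raises(ValueError):
            FRAPGroundTruth(bleach_depth=0.0)


class TestStackGenerator:
    def test_full_colocalization_has_no_green_only_labels(self):
        _, _, labels = simulate_stack_pair(
            ColocGroundTruth(colocalized_fraction=1.0, seed=0))
        assert (labels == LABEL_GREEN_ONLY).sum() == 0
        assert (labels == LABEL_COLOC).sum() > 0

    def test_zero_colocalization_has_no_coloc_labels(self):
        _, _, labels = simulate_stack_pair(
            ColocGroundTruth(colocalized_fraction=0.0, seed=0))
        assert (labels == LABEL_COLOC).sum() == 0
        assert (labels == LABEL_GREEN_ONLY).sum() > 0

    def test_fixed_seed_is_bit_reproducible(self):
        truth = ColocGroundTruth(seed=4)
        g1, r1, l1 = simulate_stack_pair(truth)
        g2, r2, l2 = simulate_stack_pair(truth)
        assert np.array_equal(g1, g2)
        assert np.array_equal(r1, r2)
        assert np.array_equal(l1, l2)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            ColocGroundTruth(colocalized_fraction=1.5)
        with pytest.raises(ValueError):
            ColocGroundTruth(volume_dims=(4, 64, 64))
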