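import dataclasses

import numpy as np
import pandas as pd
import pytest

from beartrack import hmm
from beartrack.core import read_deployments, read_fixes, read_temperature
from beartrack.simulate import (
    SimConfig,
    clean_step_series,
    simulate_observation,
    simulate_study,
    simulate_temperature,
    simulate_track,
)
from beartrack.tag_performance import detect_detachment


class TestTemperature:
    def test_same_seed_gives_identical_series(self):
        cfg = SimConfig(seed=3)
        a = simulate_temperature(cfg, 500.0)
        b = simulate_temperature(cfg, 500.0)
        pd.testing.assert_frame_equal(a, b)

    def test_white_noise_sd_recovered_without_ar_and_diel_terms(self):
        cfg = SimConfig(temp_ar_coef=0.0, temp_diel_amp_c=0.0, temp_ar_sd=1.3, seed=1)
        s = simulate_temperature(cfg, 5000.0)
        hours = np.arange(len(s))
        trend = cfg.temp_start_c + cfg.temp_cooling_c_per_day * hours / 24.0
        resid = s["temp_c"].to_numpy() - trend
        assert np.std(resid) == pytest.approx(1.3, rel=0.05)

    def test_cooling_trend_direction(self):
        cfg = SimConfig(temp_cooling_c_per_day=-0.3, seed=2)
        s = simulate_temperature(cfg, 2000.0)
        v = s["temp_c"].to_numpy()
        assert v[: len(v) // 2].mean() > v[len(v) // 2 :].mean()

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_temperature(SimConfig(), 0.0)


class TestTrack:
    def test_huge_concentration_gives_near_collinear_path(self):
        truth = dataclasses.replace(
            SimConfig().hmm_truth,
            turn_mean=np.array([0.0, 0.0]),
            turn_conc=np.array([1e3, 1e3]),
        )
        cfg = SimConfig(hmm_truth=truth, n_steps=400, seed=4)
        temp = simulate_temperature(cfg, cfg.n_steps * 4.0 + 48)
        rng = np.random.default_rng(4)
        _, _, _, turns, _ = simulate_track(cfg, temp, rng)
        assert np.mean(np.abs(turns[1:]) < 0.1) > 0.99

    def test_occupancy_matches_stationary_law_at_constant_temperature(self):
        cfg = SimConfig(
            n_steps=4000,
            temp_cooling_c_per_day=0.0,
            temp_diel_amp_c=0.0,
            temp_ar_coef=0.0,
            temp_ar_sd=0.0,
            seed=5,
        )
        temp = simulate_temperature(cfg, cfg.n_steps * 4.0 + 48)
        rng = np.random.default_rng(5)
        _, states, _, _, temps = simulate_track(cfg, temp, rng)
        G = hmm.transition_matrices(cfg.hmm_truth, np.array([temps[0]]))[0]
        pi = hmm.stationary_distribution(G)
        occ = np.mean(states == 1)
        assert occ == pytest.approx(pi[0], abs=0.05)

    def test_traveling_step_mean_matches_configured_truth(self):
        # ~0.74 km per 4-h step for the traveling state (~0.19 km/h)
        cfg = SimConfig(n_steps=4000, seed=6)
        temp = simulate_temperature(cfg, cfg.n_steps * 4.0 + 48)
        rng = np.random.default_rng(6)
        steps2 = []
        for _ in range(6):
            _, states, steps, _, _ = simulate_track(cfg, temp, rng)
            steps2.append(steps[states == 2])
        steps2 = np.concatenate(steps2)
        assert len(steps2) > 10_000
        assert steps2.mean() == pytest.approx(0.74, rel=0.05)

    def test_track_span_must_be_covered_by_temperature(self):
        cfg = SimConfig(n_steps=500)
        temp = simulate_temperature(cfg, 100.0)
        with pytest.raises(ValueError, match="cover"):
            simulate_track(cfg, temp, np.random.default_rng(0))


class TestObservation:
    def test_noise_free_observation_reproduces_truth_at_duty_times(self):
        cfg = SimConfig.recovery(n_bears=1, n_steps=100, seed=7)
        temp = simulate_temperature(cfg, cfg.n_steps * 4.0 + 48)
        rng = np.random.default_rng(7)
        pos, *_ = simulate_track(cfg, temp, rng)
        fx, failure = simulate_observation(pos, "seatrkr", cfg, rng, "t1", "b1")
        assert failure["cause"] == "stopped"
        hours = (fx["time"] - pos["time"].iloc[0]).dt.total_seconds() / 3600.0
        truth_at = pos.set_index("time").loc[fx["time"]]
        assert np.allclose(fx["lon"].to_numpy(), truth_at["lon"].to_numpy(), atol=1e-12)
        assert np.allclose(hours % 4.0, 0.0)

    def test_argos_class_mix_recovered_at_large_n(self):
        cfg = SimConfig(n_steps=100, fix_success=1.0, seed=8)
        temp = simulate_temperature(cfg, cfg.n_steps * 4.0 + 48)
        rng = np.random.default_rng(8)
        pos, *_ = simulate_track(cfg, temp, rng)
        counts = {c: 0 for c in "3210AB"}
        n_total = 0
        for _ in range(120):  # ~12,000 Argos fixes
            fx, _ = simulate_observation(pos, "ear", cfg, rng, "t", "b")
            fx = fx[fx["activity"] == "active"]
            for c, k in fx["loc_class"].value_counts().items():
                counts[c] += int(k)
                n_total += int(k)
        mix = np.asarray(cfg.class_mix)
        observed = np.array([counts[c] / n_total for c in "3210AB"])
        # three Monte-Carlo SDs at the realized sample size
        tol = 3.0 * np.sqrt(mix * (1 - mix) / n_total)
        assert n_total > 10_000
        assert np.all(np.abs(observed - mix) < np.maximum(tol, 0.01))

    def test_detachment_closed_loop(self):
        cfg = dataclasses.replace(
            SimConfig(seed=9, fix_success=1.0, n_steps=400),
            detach_mean_days={"pentagon": 3.0, "tribrush": 3.0, "seatrkr": 3.0},
        )
        temp = simulate_temperature(cfg, cfg.n_steps * 4.0 + 48)
        rng = np.random.default_rng(9)
        pos, *_ = simulate_track(cfg, temp, rng)
        fx, failure = simulate_observation(pos, "pentagon", cfg, rng, "t", "b")
        assert failure["cause"] == "detached"
        status, when = detect_detachment(fx)
        assert status == "detached"
        detected_h = (when - pos["time"].iloc[0]).total_seconds() / 3600.0
        first_inactive_possible = failure["event_h"] + cfg.inactivity_onset_h
        assert first_inactive_possible - 1e-9 <= detected_h
        # recovered within one duty cycle of the earliest possible inactive fix,
        # allowing for fixes dropped at 1 - fix_success
        assert detected_h <= first_inactive_possible + 2 * cfg.duty_cycle_h["pentagon"]


class TestStudy:
    def test_emitted_files_parse_cleanly(self, tmp_path):
        study = simulate_study(SimConfig(n_bears=3, n_steps=120, seed=10))
        study.write(tmp_path)
        fixes = read_fixes(tmp_path / "fixes.csv")
        deps = read_deployments(tmp_path / "deployments.csv")
        temp = read_temperature(tmp_path / "temperature.csv")
        assert len(fixes) > 0 and len(deps) == 3 and len(temp) > 0
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "config_echo.yaml").exists()

    def test_deterministic_under_seed(self):
        a = simulate_study(SimConfig(n_bears=2, n_steps=100, seed=12))
        b = simulate_study(SimConfig(n_bears=2, n_steps=100, seed=12))
        pd.testing.assert_frame_equal(a.fixes, b.fixes)
        pd.testing.assert_frame_equal(a.temperature, b.temperature)
        assert all(np.array_equal(a.truth.states[k], b.truth.states[k]) for k in a.truth.states)

    def test_clean_step_series_matches_generating_moments(self, clean_study, clean_series):
        # noise-free observation: series steps align 1:1 with generating steps,
        # so per-state sample means should match the configured gamma means
        truth = clean_study.truth
        states = np.concatenate([truth.states[k] for k in sorted(truth.states)])
        steps = clean_series.data["step_km"].to_numpy()
        assert len(states) == len(steps)
        for s in (1, 2):
            assert steps[states == s].mean() == pytest.approx(
                truth.params.step_mean[s - 1], rel=0.06
            )
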