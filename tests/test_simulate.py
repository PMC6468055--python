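"""Synthetic deployment generator: determinism, budgets, analytic recovery."""

import numpy as np
import pytest

from polarfmr.behavior import ACTIVE, REST, SWIM, detect_swimming
from polarfmr.movement import great_circle_km, movement_rates, regularize_track
from polarfmr.pipeline import process_deployment
from polarfmr.simulate import (
    GroundTruth,
    SimConfig,
    ground_truth,
    mean_abs_sin_plus_noise,
    simulate_accel,
    simulate_behavior,
    simulate_dlw,
    simulate_gps,
)

HOUR = 1 / 24


class TestSimulateBehavior:
    def test_pure_rest_budget(self):
        cfg = SimConfig(seed=1, duration_days=HOUR,
                        behavior_budget={REST: 1.0, ACTIVE: 0.0, SWIM: 0.0})
        labels = simulate_behavior(cfg)
        assert (labels == REST).all()

    def test_swim_fraction_converges(self):
        cfg = SimConfig(seed=5, duration_days=10.0)
        labels = simulate_behavior(cfg)
        swim_frac = np.mean(labels == SWIM)
        assert swim_frac == pytest.approx(0.003, abs=0.002)

    def test_deterministic(self):
        a = simulate_behavior(SimConfig(seed=9, duration_days=HOUR))
        b = simulate_behavior(SimConfig(seed=9, duration_days=HOUR))
        assert np.array_equal(a, b)

    def test_bad_budget_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, behavior_budget={REST: 0.5, ACTIVE: 0.2, SWIM: 0.1})


class TestSimulateAccel:
    def test_resting_noise_free_odba_near_zero(self):
        cfg = SimConfig(seed=2, duration_days=HOUR / 4, noise_sd_g=0.0,
                        gravity_wander_deg_per_min=0.0,
                        behavior_budget={REST: 1.0, ACTIVE: 0.0, SWIM: 0.0},
                        dyn_amplitude_g={REST: 0.0, ACTIVE: 0.35, SWIM: 0.15})
        labels = simulate_behavior(cfg)
        trace, _ = simulate_accel(labels, cfg)
        from polarfmr.accel import compute_odba

        series = compute_odba(trace)
        assert np.all(np.abs(series.odba[32:-32]) < 1e-9)

    def test_sinusoid_mean_odba_matches_2a_over_pi(self):
        cfg = SimConfig(seed=3, duration_days=HOUR, noise_sd_g=0.0,
                        gravity_wander_deg_per_min=0.0,
                        behavior_budget={REST: 0.0, ACTIVE: 1.0, SWIM: 0.0})
        labels = simulate_behavior(cfg)
        trace, _ = simulate_accel(labels, cfg)
        from polarfmr.accel import compute_odba

        series = compute_odba(trace)
        a = cfg.dyn_amplitude_g[ACTIVE]
        assert series.odba[32:-32].mean() == pytest.approx(2 * a / np.pi, rel=0.01)

    def test_amplitude_beyond_range_clips(self):
        cfg = SimConfig(seed=4, duration_days=HOUR / 8, noise_sd_g=0.0,
                        behavior_budget={REST: 0.0, ACTIVE: 1.0, SWIM: 0.0},
                        dyn_amplitude_g={REST: 0.0, ACTIVE: 25 / 9.81, SWIM: 0.15})
        labels = simulate_behavior(cfg)
        trace, _ = simulate_accel(labels, cfg)
        from polarfmr.accel import clipping_fraction

        assert clipping_fraction(trace) > 0

    def test_swim_seconds_marked_wet(self):
        cfg = SimConfig(seed=6, duration_days=HOUR,
                        behavior_budget={REST: 0.5, ACTIVE: 0.4, SWIM: 0.1})
        labels = simulate_behavior(cfg)
        _, cond = simulate_accel(labels, cfg)
        assert np.array_equal(cond.wet, labels == SWIM)

    def test_deterministic_outputs(self):
        cfg = SimConfig(seed=11, duration_days=HOUR / 8)
        labels = simulate_behavior(cfg)
        t1, c1 = simulate_accel(labels, cfg)
        t2, c2 = simulate_accel(labels, cfg)
        assert np.array_equal(t1.ax, t2.ax)
        assert np.array_equal(c1.wet, c2.wet)


class TestSimulateGPS:
    def test_all_rest_no_displacement(self):
        cfg = SimConfig(seed=2, duration_days=HOUR,
                        behavior_budget={REST: 1.0, ACTIVE: 0.0, SWIM: 0.0})
        labels = simulate_behavior(cfg)
        track = simulate_gps(labels, cfg)
        assert great_circle_km(track.lat[0], track.lon[0],
                               track.lat[-1], track.lon[-1]) < 1e-9

    def test_straight_line_distance(self):
        cfg = SimConfig(seed=2, duration_days=2 * HOUR, walk_speed_kmh=4.0,
                        heading_sd_deg_per_s=0.0,
                        behavior_budget={REST: 0.0, ACTIVE: 1.0, SWIM: 0.0})
        labels = simulate_behavior(cfg)
        track = simulate_gps(labels, cfg)
        d = great_circle_km(track.lat[0], track.lon[0], track.lat[-1], track.lon[-1])
        assert d == pytest.approx(8.0, rel=1e-3)

    def test_grid_rates_bounded_by_walk_speed(self):
        cfg = SimConfig(seed=8, duration_days=6 * HOUR, walk_speed_kmh=3.0)
        labels = simulate_behavior(cfg)
        track = simulate_gps(labels, cfg)
        grid = regularize_track(track, 30.0)
        rates = movement_rates(grid)
        assert np.all(rates.step_distances_km / 0.5 <= cfg.walk_speed_kmh + 1e-9)


class TestGroundTruth:
    def test_all_rest_floor(self):
        cfg = SimConfig(seed=1, duration_days=HOUR, noise_sd_g=0.0,
                        behavior_budget={REST: 1.0, ACTIVE: 0.0, SWIM: 0.0},
                        dyn_amplitude_g={REST: 0.0, ACTIVE: 0.35, SWIM: 0.15})
        labels = simulate_behavior(cfg)
        gt = ground_truth(cfg, labels)
        assert gt.expected_fmr_acc == pytest.approx(0.07 * 20.083 * 24, rel=1e-9)

    def test_all_swim_cost(self):
        cfg = SimConfig(seed=1, duration_days=HOUR,
                        behavior_budget={REST: 0.0, ACTIVE: 0.0, SWIM: 1.0})
        labels = simulate_behavior(cfg)
        gt = ground_truth(cfg, labels)
        assert gt.expected_fmr_acc == pytest.approx(2.75 * 20.083 * 24, rel=1e-9)

    def test_mixed_budget_is_convex_combination(self):
        cfg = SimConfig(seed=13, duration_days=HOUR)
        labels = simulate_behavior(cfg)
        gt = ground_truth(cfg, labels)
        costs = []
        for s, frac in gt.state_fractions.items():
            if s == SWIM:
                costs.append(frac * 2.75 * 20.083 * 24)
            else:
                vo2 = 0.07 + 1.90 * gt.expected_mean_odba_per_state[s]
                costs.append(frac * vo2 * 20.083 * 24)
        assert gt.expected_fmr_acc == pytest.approx(sum(costs), rel=1e-12)

    def test_mean_abs_sin_plus_noise_limits(self):
        assert mean_abs_sin_plus_noise(0.4, 0.0) == pytest.approx(0.8 / np.pi)
        assert mean_abs_sin_plus_noise(0.0, 0.02) == pytest.approx(
            0.02 * np.sqrt(2 / np.pi)
        )
        # large signal-to-noise: additive approximation becomes exact
        assert mean_abs_sin_plus_noise(1.0, 1e-6) == pytest.approx(
            2 / np.pi, rel=1e-4
        )


class TestEndToEndRecovery:
    @pytest.mark.parametrize("hours,tol", [(1, 0.01), (6, 0.01)])
    def test_noise_free_recovery(self, hours, tol):
        cfg = SimConfig(seed=21, duration_days=hours * HOUR, noise_sd_g=0.0,
                        gravity_wander_deg_per_min=0.0)
        labels = simulate_behavior(cfg)
        trace, cond = simulate_accel(labels, cfg)
        res, _, _ = process_deployment(trace, cond=cond, labels=labels,
                                       duration_days=cfg.duration_days)
        gt = ground_truth(cfg, labels)
        assert res.daily_ee == pytest.approx(gt.expected_fmr_acc, rel=tol)

    def test_default_noise_recovery_within_3_percent(self):
        cfg = SimConfig(seed=22, duration_days=3 * HOUR)
        labels = simulate_behavior(cfg)
        trace, cond = simulate_accel(labels, cfg)
        res, _, _ = process_deployment(trace, cond=cond, labels=labels,
                                       duration_days=cfg.duration_days)
        gt = ground_truth(cfg, labels)
        assert res.daily_ee == pytest.approx(gt.expected_fmr_acc, rel=0.03)

    def test_swim_detection_feeds_substitution(self):
        cfg = SimConfig(seed=23, duration_days=HOUR,
                        behavior_budget={REST: 0.6, ACTIVE: 0.3, SWIM: 0.1})
        labels = simulate_behavior(cfg)
        trace, cond = simulate_accel(labels, cfg)
        # conductivity-only path (no external labels): detected swim seconds
        flags = detect_swimming(cond)
        assert np.mean(flags) == pytest.approx(np.mean(labels == SWIM), abs=0.02)

    def test_six_bear_cohort_feeds_validation(self):
        import pandas as pd

        from polarfmr.validation import table1_analysis

        rows = []
        for i in range(6):
            cfg = SimConfig(
                seed=30 + i, duration_days=HOUR,
                body_mass_kg=140 + 12 * i,
                behavior_budget={REST: 0.8 - 0.06 * i,
                                 ACTIVE: 0.197 + 0.06 * i, SWIM: 0.003},
                true_rco2_l_day=1600 + 200 * i,
            )
            labels = simulate_behavior(cfg)
            trace, cond = simulate_accel(labels, cfg)
            res, _, _ = process_deployment(trace, cond=cond, labels=labels,
                                           duration_days=cfg.duration_days)
            gt = ground_truth(cfg, labels)
            rows.append(dict(bear_id=i, duration_days=9.0,
                             mean_mass_kg=cfg.body_mass_kg,
                             fmr_dlw=gt.fmr_dlw_kj_kg_day,
                             fmr_acc=res.daily_ee,
                             mean_odba_g=res.mean_odba))
        report = table1_analysis(pd.DataFrame(rows))
        assert report["n"] == 6
        assert set(report["regressions"]) >= {"fmr_acc", "mean_odba", "mean_mass"}
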