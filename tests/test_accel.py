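"""ODBA chain: unit conversion, static/dynamic split, epochs, clipping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_odba, brute_force_running_mean, make_trace
from polarfmr.accel import (
    AccelTrace,
    clipping_fraction,
    compute_odba,
    dynamic_acceleration,
    epoch_mean_odba,
    odba,
    static_acceleration,
    to_g_units,
)


class TestToGUnits:
    @pytest.mark.parametrize(
        "ms2,expected", [(9.81, 1.0), (0.0, 0.0), (-19.62, -2.0)]
    )
    def test_conversion(self, ms2, expected):
        trace = make_trace([ms2])
        gx, _, _ = to_g_units(trace, 9.81)
        assert gx[0] == pytest.approx(expected)

    def test_nonpositive_g_rejected(self):
        with pytest.raises(ValueError):
            to_g_units(make_trace([1.0]), 0.0)


class TestStaticAcceleration:
    def test_constant_series_unchanged(self):
        x = np.full(100, 0.37)
        assert np.allclose(static_acceleration(x), 0.37)

    def test_truncated_centered_mean_small_case(self):
        # window 3 at 1 Hz on [0..4]: hand-computed truncated means
        out = static_acceleration(np.arange(5.0), window_s=3, sample_rate_hz=1)
        assert np.allclose(out, [0.5, 1.0, 2.0, 3.0, 3.5])

    def test_full_period_sinusoid_averages_to_zero(self):
        fs, f = 16.0, 0.5  # period 2 s == window length
        t = np.arange(0, 64) / fs
        out = static_acceleration(np.sin(2 * np.pi * f * t), 2.0, fs)
        assert np.all(np.abs(out[16:-16]) < 1e-6)

    def test_window_longer_than_series_gives_global_mean(self):
        x = np.array([1.0, 2.0, 6.0])
        out = static_acceleration(x, window_s=100, sample_rate_hz=1)
        assert np.allclose(out, 3.0)

    def test_empty_series(self):
        assert static_acceleration(np.array([])).size == 0


class TestDynamicAndODBA:
    def test_raw_equals_static_gives_zero(self):
        x = np.array([1.0, 2.0])
        assert np.allclose(dynamic_acceleration(x, x), 0.0)

    def test_hand_subtraction(self):
        out = dynamic_acceleration([1.2, 0.8], [1.0, 1.0])
        assert np.allclose(out, [0.2, -0.2])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dynamic_acceleration(np.zeros(3), np.zeros(4))

    def test_odba_hand_sum(self):
        assert odba([0.1], [-0.2], [0.05])[0] == pytest.approx(0.35)

    def test_odba_of_constant_trace_is_zero_in_interior(self):
        trace = make_trace(np.full(200, 5.0), np.full(200, 1.0), np.full(200, -3.0))
        series = compute_odba(trace)
        assert np.all(np.abs(series.odba[16:-16]) < 1e-12)

    @given(c=st.floats(0.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_positive_homogeneity(self, c):
        dyn = np.array([0.1, -0.3, 0.2])
        base = odba(dyn, dyn, dyn)
        assert np.allclose(odba(c * dyn, c * dyn, c * dyn), c * base)

    def test_matches_brute_force_oracle_random_trace(self, rng):
        n, w = 500, 32
        gx, gy, gz = rng.uniform(-1.5, 1.5, (3, n))
        trace = make_trace(gx * 9.81, gy * 9.81, gz * 9.81)
        series = compute_odba(trace)
        expected = brute_force_odba(gx, gy, gz, w)
        assert np.allclose(series.odba, expected, atol=1e-12)

    def test_unit_conversion_commutes_with_smoothing(self, rng):
        # converting m/s^2 -> g before vs after the running mean is identical
        x = rng.normal(0, 5, 300)
        a = static_acceleration(x / 9.81)
        b = static_acceleration(x) / 9.81
        assert np.allclose(a, b, atol=1e-14)

    def test_gap_splits_smoothing_segments(self):
        # two segments separated by a 10 s gap: each smoothed independently
        fs = 16.0
        t = np.concatenate([np.arange(64) / fs, 10.0 + np.arange(64) / fs])
        x = np.concatenate([np.full(64, 9.81), np.full(64, -9.81)])
        trace = AccelTrace(t=t, ax=x, ay=np.zeros(128), az=np.zeros(128))
        series = compute_odba(trace)
        # constant within each segment -> zero dynamic everywhere, even at
        # the segment boundary where a cross-gap mean would leak
        assert np.all(np.abs(series.odba) < 1e-12)


class TestEpochMeanODBA:
    def test_constant_two_epochs(self):
        trace = make_trace(np.zeros(32))
        series = compute_odba(trace)
        series.odba[:] = 0.5
        ep = epoch_mean_odba(series, 1.0)
        assert len(ep) == 2
        assert np.allclose(ep.mean_odba, 0.5)
        assert np.all(ep.n_samples == 16)

    def test_hand_means(self):
        trace = make_trace(np.zeros(32))
        series = compute_odba(trace)
        series.odba[:16] = 0.1
        series.odba[16:] = 0.3
        ep = epoch_mean_odba(series, 1.0)
        assert np.allclose(ep.mean_odba, [0.1, 0.3])

    def test_weighted_epoch_means_reproduce_global_mean(self, rng):
        trace = make_trace(rng.normal(0, 5, 777))  # partial final epoch
        series = compute_odba(trace)
        ep = epoch_mean_odba(series, 1.0)
        recombined = np.sum(ep.mean_odba * ep.n_samples) / np.sum(ep.n_samples)
        assert recombined == pytest.approx(series.odba.mean(), rel=1e-12)

    def test_empty_input(self):
        trace = make_trace(np.array([]))
        ep = epoch_mean_odba(compute_odba(trace))
        assert len(ep) == 0


class TestClipping:
    def test_no_clipping(self, rng):
        trace = make_trace(rng.uniform(-19, 19, 100))
        assert clipping_fraction(trace) == 0.0

    def test_counted_fraction(self):
        ax = np.zeros(100)
        ax[:2] = 20.0
        ay = np.zeros(100)
        ay[0] = -20.0
        trace = make_trace(ax, ay)
        assert clipping_fraction(trace) == pytest.approx(3 / 300)

    def test_ingest_rejects_beyond_range(self):
        with pytest.raises(ValueError):
            make_trace([25.0])


def test_sinusoid_mean_abs_dynamic_approaches_2a_over_pi():
    # a*sin(2*pi*f*t) over integer cycles: mean |dynamic| -> 2a/pi
    fs, a = 16.0, 0.4
    # frequencies with an integer number of cycles per 2-s window (so the
    # running mean removes none of the gait signal) whose sampled phases
    # cover 32 distinct points per repeat (aliasing bias < 0.3%)
    for f in (0.5, 1.5):
        t = np.arange(int(600 * fs)) / fs
        x = a * np.sin(2 * np.pi * f * t)
        static = static_acceleration(x, 2.0, fs)
        m = np.abs(x - static)[32:-32].mean()
        assert m == pytest.approx(2 * a / np.pi, rel=0.01)
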