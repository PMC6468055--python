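import numpy as np
import pytest

from polarfmr.accel import AccelTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(ax, ay=None, az=None, fs=16.0, sensor_range=20.0):
    """AccelTrace helper with y/z defaulting to zero."""
    ax = np.asarray(ax, dtype=float)
    ay = np.zeros_like(ax) if ay is None else np.asarray(ay, dtype=float)
    az = np.zeros_like(ax) if az is None else np.asarray(az, dtype=float)
    t = np.arange(ax.size) / fs
    return AccelTrace(t=t, ax=ax, ay=ay, az=az, sample_rate_hz=fs,
                      sensor_range=sensor_range)


def brute_force_running_mean(x, w):
    """Independent oracle: truncated centered mean by naive loops, with the
    window split w//2 before / rest after."""
    x = np.asarray(x, dtype=float)
    n = x.size
    before = w // 2
    after = w - 1 - before
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - before)
        hi = min(n, i + after + 1)
        out[i] = sum(x[lo:hi]) / (hi - lo)
    return out


def brute_force_odba(gx, gy, gz, w):
    """Independent oracle for the full smoothing/subtract/abs-sum chain."""
    out = np.zeros(len(gx))
    for axis in (gx, gy, gz):
        static = brute_force_running_mean(axis, w)
        for i in range(len(axis)):
            out[i] += abs(axis[i] - static[i])
    return out
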