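"""Overall dynamic body acceleration (ODBA) from raw tri-axial acceleration.

The processing chain follows the standard dynamic-body-acceleration recipe
for collar accelerometers: raw acceleration (m/s^2) is converted to g units,
the static (gravitational) component is estimated per axis with a 2-s
centered running mean, dynamic acceleration is the raw minus static signal,
and ODBA is the sum of the absolute dynamic accelerations across the three
axes.  Per-second epoch means feed the behavior-specific energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STANDARD_GRAVITY = 9.81  # m/s^2 per g
DEFAULT_WINDOW_S = 2.0
DEFAULT_SAMPLE_RATE_HZ = 16.0
DEFAULT_SENSOR_RANGE = 20.0  # m/s^2


@dataclass
class AccelTrace:
    """Timestamped tri-axial acceleration in m/s^2.

    ``t`` is seconds since deployment start on a uniform 1/sample_rate grid
    (gaps from logger dropouts are allowed and handled downstream by
    segment-wise smoothing).  Axis values are clipped by the sensor at
    ``±sensor_range`` and must never exceed it.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    sensor_range: float = DEFAULT_SENSOR_RANGE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.t.size
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise ValueError("t, ax, ay, az must have equal lengths")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        rng = self.sensor_range
        for name, a in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if np.any(np.abs(a) > rng + 1e-9):
                raise ValueError(
                    f"{name} exceeds the sensor range ±{rng} m/s^2; "
                    "clip or fix the ingest"
                )

    def __len__(self) -> int:
        return self.t.size

    def segment_slices(self) -> list[slice]:
        """Contiguous runs of samples, split where the time step exceeds
        1.5 sample intervals (logger dropouts).  Running means must not mix
        data across such gaps."""
        if len(self) == 0:
            return []
        dt = np.diff(self.t)
        breaks = np.flatnonzero(dt > 1.5 / self.sample_rate_hz) + 1
        edges = np.concatenate(([0], breaks, [len(self)]))
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class ODBASeries:
    """Per-sample ODBA (g) with the static/dynamic decomposition kept for QC."""

    t: np.ndarray
    odba: np.ndarray
    static_x: np.ndarray
    static_y: np.ndarray
    static_z: np.ndarray
    dynamic_x: np.ndarray
    dynamic_y: np.ndarray
    dynamic_z: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    g_const: float = STANDARD_GRAVITY

    def __len__(self) -> int:
        return self.t.size


@dataclass
class EpochODBA:
    """Sequence of consecutive epochs with mean ODBA per epoch.

    Parallel arrays: ``epoch_start`` (s), ``mean_odba`` (g), ``n_samples``.
    The duration-weighted mean of the epoch means equals the global mean.
    """

    epoch_start: np.ndarray
    mean_odba: np.ndarray
    n_samples: np.ndarray
    epoch_length_s: float = 1.0

    def __len__(self) -> int:
        return self.epoch_start.size


def to_g_units(trace: AccelTrace, g_const: float = STANDARD_GRAVITY):
    """Convert each axis from m/s^2 to g units (1 g = 9.81 m/s^2).

    Returns the three axis arrays ``(gx, gy, gz)`` in g.
    """
    if not g_const > 0:
        raise ValueError(f"g_const must be positive, got {g_const}")
    return trace.ax / g_const, trace.ay / g_const, trace.az / g_const


def _window_samples(window_s: float, sample_rate_hz: float) -> int:
    w = int(round(window_s * sample_rate_hz))
    if w < 1:
        raise ValueError(
            f"window of {window_s} s at {sample_rate_hz} Hz spans <1 sample"
        )
    return w


def static_acceleration(
    axis: np.ndarray,
    window_s: float = DEFAULT_WINDOW_S,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> np.ndarray:
    """Centered running mean of one axis — the static (gravity) estimate.

    The window holds ``round(window_s * sample_rate_hz)`` samples (32 at the
    2 s / 16 Hz defaults, split 16 before / current / 15 after).  At the
    series edges the window is truncated to the samples that exist, so the
    output has the same length as the input and no data is fabricated.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.asarray(axis, dtype=float)
    if x.size == 0:
        return x.copy()
    w = _window_samples(window_s, sample_rate_hz)
    before = w // 2
    after = w - 1 - before
    n = x.size
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.clip(np.arange(n) - before, 0, n)
    hi = np.clip(np.arange(n) + after + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def dynamic_acceleration(raw: np.ndarray, static: np.ndarray) -> np.ndarray:
    """Dynamic acceleration: raw minus static, elementwise, in g."""
    raw = np.asarray(raw, dtype=float)
    static = np.asarray(static, dtype=float)
    if raw.shape != static.shape:
        raise ValueError(f"shape mismatch: {raw.shape} vs {static.shape}")
    return raw - static


def odba(
    dynamic_x: np.ndarray, dynamic_y: np.ndarray, dynamic_z: np.ndarray
) -> np.ndarray:
    """Per-sample ODBA: |dx| + |dy| + |dz| (g)."""
    dx = np.asarray(dynamic_x, dtype=float)
    dy = np.asarray(dynamic_y, dtype=float)
    dz = np.asarray(dynamic_z, dtype=float)
    if not (dx.shape == dy.shape == dz.shape):
        raise ValueError("dynamic axes must have equal shapes")
    return np.abs(dx) + np.abs(dy) + np.abs(dz)


def vedba(
    dynamic_x: np.ndarray, dynamic_y: np.ndarray, dynamic_z: np.ndarray
) -> np.ndarray:
    """Vectorial dynamic body acceleration sqrt(dx²+dy²+dz²) — QC utility only;
    the energetics calibration is in terms of ODBA."""
    return np.sqrt(
        np.square(dynamic_x) + np.square(dynamic_y) + np.square(dynamic_z)
    )


def compute_odba(
    trace: AccelTrace,
    window_s: float = DEFAULT_WINDOW_S,
    g_const: float = STANDARD_GRAVITY,
) -> ODBASeries:
    """Full chain: m/s^2 → g → static (running mean) → dynamic → ODBA.

    Smoothing is applied independently to each contiguous segment of the
    trace so that running means never mix data across logger dropouts.
    """
    gx, gy, gz = to_g_units(trace, g_const)
    n = len(trace)
    sx = np.empty(n)
    sy = np.empty(n)
    sz = np.empty(n)
    for seg in trace.segment_slices():
        sx[seg] = static_acceleration(gx[seg], window_s, trace.sample_rate_hz)
        sy[seg] = static_acceleration(gy[seg], window_s, trace.sample_rate_hz)
        sz[seg] = static_acceleration(gz[seg], window_s, trace.sample_rate_hz)
    dx = dynamic_acceleration(gx, sx)
    dy = dynamic_acceleration(gy, sy)
    dz = dynamic_acceleration(gz, sz)
    return ODBASeries(
        t=trace.t.copy(),
        odba=odba(dx, dy, dz),
        static_x=sx, static_y=sy, static_z=sz,
        dynamic_x=dx, dynamic_y=dy, dynamic_z=dz,
        sample_rate_hz=trace.sample_rate_hz,
        g_const=g_const,
    )


def epoch_mean_odba(series: ODBASeries, epoch_length_s: float = 1.0) -> EpochODBA:
    """Mean ODBA over consecutive epochs of ``epoch_length_s`` seconds.

    Epoch boundaries are anchored at the first timestamp.  The final epoch
    may be partial; ``n_samples`` records how many samples each epoch holds,
    so the n-weighted mean of epoch means reproduces the global mean exactly.
    """
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    if len(series) == 0:
        empty = np.array([])
        return EpochODBA(empty, empty, np.array([], dtype=int), epoch_length_s)
    idx = np.floor((series.t - series.t[0]) / epoch_length_s + 1e-12).astype(int)
    n_epochs = idx[-1] + 1
    counts = np.bincount(idx, minlength=n_epochs)
    sums = np.bincount(idx, weights=series.odba, minlength=n_epochs)
    present = counts > 0
    means = np.full(n_epochs, np.nan)
    means[present] = sums[present] / counts[present]
    starts = series.t[0] + epoch_length_s * np.arange(n_epochs)
    return EpochODBA(
        epoch_start=starts[present],
        mean_odba=means[present],
        n_samples=counts[present],
        epoch_length_s=epoch_length_s,
    )


def clipping_fraction(trace: AccelTrace) -> float:
    """Fraction of axis-samples at or beyond the sensor range (saturation QC)."""
    n = 3 * len(trace)
    if n == 0:
        return 0.0
    rng = trace.sensor_range
    clipped = sum(
        int(np.count_nonzero(np.abs(a) >= rng))
        for a in (trace.ax, trace.ay, trace.az)
    )
    return clipped / n
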