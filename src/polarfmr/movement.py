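"""GPS track regularization and great-circle movement rates.

Fixes are interpolated onto a uniform 30-min grid by linear interpolation
along the great-circle path between bracketing fixes (spherical linear
interpolation), step distances are haversine great-circle distances on a
sphere of radius 6371.0088 km, and movement rate is step distance divided
by the step duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088


@dataclass
class GPSTrack:
    """Timestamped positions.  ``t`` is seconds (float) or datetime64."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t)
        if np.issubdtype(t.dtype, np.datetime64):
            t = t.astype("datetime64[ns]").astype(np.int64) / 1e9
        self.t = np.asarray(t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (self.t.size == self.lat.size == self.lon.size):
            raise ValueError("t, lat, lon must have equal lengths")
        if np.any(np.abs(self.lat) > 90):
            raise ValueError("latitude out of range")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        # wrap longitudes to (-180, 180]
        self.lon = -(((-self.lon + 180.0) % 360.0) - 180.0)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class MovementSummary:
    mean_rate_kmh: float
    step_distances_km: np.ndarray
    n_steps: int
    interval_min: float


def great_circle_km(lat1, lon1, lat2, lon2) -> float | np.ndarray:
    """Haversine great-circle distance in km (spherical earth)."""
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float) for v in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude out of range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def _to_unit(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    phi, lam = np.radians(lat), np.radians(lon)
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)],
        axis=-1,
    )


def _from_unit(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lat, lon


def _slerp(v1: np.ndarray, v2: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Spherical linear interpolation between unit vectors, fraction f."""
    dot = np.clip(np.sum(v1 * v2, axis=-1, keepdims=True), -1.0, 1.0)
    omega = np.arccos(dot)
    small = omega[..., 0] < 1e-12
    sin_om = np.where(small[..., None], 1.0, np.sin(omega))
    f = f[..., None]
    w1 = np.where(small[..., None], 1.0 - f, np.sin((1 - f) * omega) / sin_om)
    w2 = np.where(small[..., None], f, np.sin(f * omega) / sin_om)
    out = w1 * v1 + w2 * v2
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def regularize_track(track: GPSTrack, interval_min: float = 30.0) -> GPSTrack:
    """Interpolate fixes onto a uniform grid along great-circle paths.

    The grid starts at the first fix and steps by ``interval_min`` minutes
    up to (and including, when it lands exactly on) the last fix.
    """
    if interval_min <= 0:
        raise ValueError("interval_min must be positive")
    if len(track) < 2:
        raise ValueError("need at least 2 fixes to regularize a track")
    step = interval_min * 60.0
    t0, t1 = track.t[0], track.t[-1]
    grid = t0 + step * np.arange(int(np.floor((t1 - t0) / step + 1e-9)) + 1)
    idx = np.clip(np.searchsorted(track.t, grid, side="right") - 1, 0, len(track) - 2)
    ta, tb = track.t[idx], track.t[idx + 1]
    frac = np.clip((grid - ta) / (tb - ta), 0.0, 1.0)
    v = _slerp(
        _to_unit(track.lat[idx], track.lon[idx]),
        _to_unit(track.lat[idx + 1], track.lon[idx + 1]),
        frac,
    )
    lat, lon = _from_unit(v)
    return GPSTrack(t=grid, lat=lat, lon=lon)


def movement_rates(grid_track: GPSTrack) -> MovementSummary:
    """Step distances and mean movement rate (km/hr) on a uniform grid."""
    if len(grid_track) < 2:
        raise ValueError("need at least 2 grid positions")
    dt = np.diff(grid_track.t)
    if not np.allclose(dt, dt[0], rtol=1e-9):
        raise ValueError("track is not on a uniform time grid")
    steps = great_circle_km(
        grid_track.lat[:-1], grid_track.lon[:-1],
        grid_track.lat[1:], grid_track.lon[1:],
    )
    steps = np.atleast_1d(steps)
    hours = (grid_track.t[-1] - grid_track.t[0]) / 3600.0
    return MovementSummary(
        mean_rate_kmh=float(np.sum(steps) / hours),
        step_distances_km=steps,
        n_steps=steps.size,
        interval_min=float(dt[0] / 60.0),
    )
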