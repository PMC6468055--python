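"""Delimited-text readers and writers for the collar data schemas.

All files are comma-separated with a header row:

- acceleration: ``time_s, ax_ms2, ay_ms2, az_ms2``
- wet/dry:      ``time_s, wet`` (0/1)
- labels:       ``time_s, state`` (rest/active/swim)
- behavior out: ``time_s, state, source``
- GPS:          ``bear_id, datetime, lat, lon`` (ISO-8601) or ``time_s, lat, lon``
- DLW samples:  ``bear_id, role, t_days, o18_ppm, h2_ppm``
- DLW doses:    ``bear_id, mass_o18_g, mass_h2_g, enrich_o18, enrich_h2, body_mass_kg``
- per-bear summary: the validation BearSummary schema
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from polarfmr.accel import AccelTrace, EpochODBA, ODBASeries
from polarfmr.behavior import BehaviorSeries, ConductivityTrace
from polarfmr.movement import GPSTrack


def read_accel_csv(path, sample_rate_hz: float = 16.0, sensor_range: float = 20.0) -> AccelTrace:
    df = pd.read_csv(path)
    return AccelTrace(
        t=df["time_s"].to_numpy(),
        ax=df["ax_ms2"].to_numpy(),
        ay=df["ay_ms2"].to_numpy(),
        az=df["az_ms2"].to_numpy(),
        sample_rate_hz=sample_rate_hz,
        sensor_range=sensor_range,
    )


def write_accel_csv(trace: AccelTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.t, "ax_ms2": trace.ax, "ay_ms2": trace.ay, "az_ms2": trace.az}
    ).to_csv(path, index=False)


def write_odba_csv(series: ODBASeries, path) -> None:
    pd.DataFrame({"time_s": series.t, "odba_g": series.odba}).to_csv(path, index=False)


def write_epoch_csv(epochs: EpochODBA, path) -> None:
    pd.DataFrame(
        {
            "epoch_start_s": epochs.epoch_start,
            "mean_odba_g": epochs.mean_odba,
            "n_samples": epochs.n_samples,
        }
    ).to_csv(path, index=False)


def read_epoch_csv(path, epoch_length_s: float = 1.0) -> EpochODBA:
    df = pd.read_csv(path)
    return EpochODBA(
        epoch_start=df["epoch_start_s"].to_numpy(dtype=float),
        mean_odba=df["mean_odba_g"].to_numpy(dtype=float),
        n_samples=df["n_samples"].to_numpy(dtype=int),
        epoch_length_s=epoch_length_s,
    )


def read_wetdry_csv(path) -> ConductivityTrace:
    df = pd.read_csv(path)
    return ConductivityTrace(
        t=df["time_s"].to_numpy(), wet=df["wet"].to_numpy().astype(bool)
    )


def write_wetdry_csv(cond: ConductivityTrace, path) -> None:
    pd.DataFrame({"time_s": cond.t, "wet": cond.wet.astype(int)}).to_csv(
        path, index=False
    )


def read_labels_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(dtype=float), df["state"].to_numpy(dtype=object)


def write_labels_csv(t: np.ndarray, labels: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": t, "state": labels}).to_csv(path, index=False)


def write_behavior_csv(series: BehaviorSeries, path) -> None:
    pd.DataFrame(
        {"time_s": series.t, "state": series.state, "source": series.source}
    ).to_csv(path, index=False)


def read_gps_csv(path) -> GPSTrack:
    df = pd.read_csv(path)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
    else:
        t = pd.to_datetime(df["datetime"]).to_numpy()
    return GPSTrack(t=t, lat=df["lat"].to_numpy(), lon=df["lon"].to_numpy())


def write_gps_csv(track: GPSTrack, path) -> None:
    pd.DataFrame({"time_s": track.t, "lat": track.lat, "lon": track.lon}).to_csv(
        path, index=False
    )


def read_dlw_csvs(samples_path, doses_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    return pd.read_csv(samples_path), pd.read_csv(doses_path)


def read_summary_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
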