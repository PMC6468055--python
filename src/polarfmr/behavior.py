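"""Per-second behavior states (rest / active / swim) and activity rate.

Swimming is the one behavior with a distinct energetic cost, so the module
centres on identifying swim seconds.  When external per-second behavior
labels are available (e.g. from a classifier) they are used directly, with
conductivity-derived swim flags taking precedence — the wet/dry sensor is a
direct physical observation of immersion.  Without labels, a simple ODBA
threshold separates rest from active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REST, ACTIVE, SWIM = "rest", "active", "swim"
STATES = (REST, ACTIVE, SWIM)

DEFAULT_MIN_BOUT_S = 5
DEFAULT_MAX_GAP_S = 2
DEFAULT_REST_THRESHOLD_G = 0.05


@dataclass
class ConductivityTrace:
    """1 Hz wet/dry conductivity channel: True = wet (immersed)."""

    t: np.ndarray
    wet: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.wet = np.asarray(self.wet, dtype=bool)
        if self.t.size != self.wet.size:
            raise ValueError("t and wet must have equal lengths")
        if self.t.size > 1 and not np.allclose(np.diff(self.t), 1.0, atol=1e-6):
            raise ValueError("conductivity must be sampled at 1 Hz")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class BehaviorSeries:
    """One state per second; ``source`` records label provenance."""

    t: np.ndarray
    state: np.ndarray
    source: str = "conductivity"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.state = np.asarray(self.state, dtype=object)
        if self.t.size != self.state.size:
            raise ValueError("t and state must have equal lengths")
        bad = set(np.unique(self.state)) - set(STATES)
        if bad:
            raise ValueError(f"unknown behavior states: {sorted(bad)}")

    def __len__(self) -> int:
        return self.t.size

    @property
    def swim_fraction(self) -> float:
        return float(np.mean(self.state == SWIM)) if len(self) else 0.0


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop exclusive."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(m.size)
    return list(zip(starts, stops))


def detect_swimming(
    cond: ConductivityTrace,
    min_bout_s: int = DEFAULT_MIN_BOUT_S,
    max_gap_s: int = DEFAULT_MAX_GAP_S,
) -> np.ndarray:
    """Per-second swim flags from the wet/dry channel.

    Dry gaps of at most ``max_gap_s`` seconds inside wet runs are bridged
    (brief sensor dropouts while the bear is in the water), then wet runs
    shorter than ``min_bout_s`` seconds are dropped (splashes, rain).  The
    result is idempotent: re-detecting on its own output changes nothing.
    """
    if min_bout_s < 1:
        raise ValueError("min_bout_s must be >= 1")
    if max_gap_s < 0:
        raise ValueError("max_gap_s must be >= 0")
    wet = cond.wet.copy()
    if max_gap_s > 0:
        for start, stop in _runs(~wet):
            interior = start > 0 and stop < wet.size
            if interior and (stop - start) <= max_gap_s:
                wet[start:stop] = True
    flags = np.zeros(wet.size, dtype=bool)
    for start, stop in _runs(wet):
        if stop - start >= min_bout_s:
            flags[start:stop] = True
    return flags


def merge_behavior(
    t: np.ndarray,
    swim_flags: np.ndarray,
    labels: np.ndarray | None = None,
    epoch_odba_g: np.ndarray | None = None,
    rest_threshold_g: float = DEFAULT_REST_THRESHOLD_G,
) -> BehaviorSeries:
    """Combine external labels and swim flags into one per-second series.

    A swim flag overrides any non-swim label.  Without external labels the
    rest/active split falls back to a threshold on the 1-s mean ODBA
    (default 0.05 g); the split only affects the reported activity rate,
    not the calibrated energy totals, because rest and active share the
    same linear cost model.
    """
    t = np.asarray(t, dtype=float)
    swim_flags = np.asarray(swim_flags, dtype=bool)
    if t.size != swim_flags.size:
        raise ValueError("t and swim_flags must be aligned")
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        if labels.size != t.size:
            raise ValueError("labels are not aligned with the time base")
        state = labels.copy()
        source = "external"
    else:
        if epoch_odba_g is None:
            state = np.full(t.size, ACTIVE, dtype=object)
        else:
            epoch_odba_g = np.asarray(epoch_odba_g, dtype=float)
            if epoch_odba_g.size != t.size:
                raise ValueError("epoch_odba_g is not aligned with the time base")
            state = np.where(
                epoch_odba_g < rest_threshold_g, REST, ACTIVE
            ).astype(object)
        source = "conductivity"
    state[swim_flags] = SWIM
    return BehaviorSeries(t=t, state=state, source=source)


def activity_rate(series: BehaviorSeries) -> float:
    """Proportion of time not at rest, in [0, 1]."""
    if len(series) == 0:
        raise ValueError("activity rate is undefined for an empty series")
    return float(np.mean(series.state != REST))
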