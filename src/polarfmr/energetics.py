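"""Behavior-specific conversion of ODBA to daily energy expenditure (FMR_ACC).

Non-swimming costs use the treadmill calibration for adult female polar
bears, V̇O2 (ml O2 g⁻¹ hr⁻¹) = 0.07 + 1.90 × ODBA (g); swimming seconds are
charged a constant 2.75 ml O2 g⁻¹ hr⁻¹.  Oxygen converts to energy at
20.083 J per ml O2.  Totals are mass-specific (kJ/kg == J/g) and daily
rates divide by the deployment duration in days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from polarfmr.accel import EpochODBA
from polarfmr.behavior import SWIM, STATES, BehaviorSeries

# Published constants
CALIB_INTERCEPT = 0.07     # ml O2 g^-1 hr^-1 at zero ODBA
CALIB_SLOPE = 1.90         # ml O2 g^-1 hr^-1 per g of ODBA
SWIM_VO2 = 2.75            # ml O2 g^-1 hr^-1, constant swim cost
REST_RMR_REF = 0.230       # ml O2 g^-1 hr^-1, resting reference (documentation)
J_PER_ML_O2 = 20.083       # J per ml O2


@dataclass(frozen=True)
class CalibrationModel:
    """The V̇O2–ODBA line plus the swim and energy-conversion constants."""

    intercept_a: float = CALIB_INTERCEPT
    slope_b: float = CALIB_SLOPE
    swim_vo2: float = SWIM_VO2
    rest_rmr_ref: float = REST_RMR_REF
    j_per_ml_o2: float = J_PER_ML_O2

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ValueError("slope_b must be positive")
        if self.intercept_a < 0:
            raise ValueError("intercept_a must be non-negative")
        if self.swim_vo2 <= self.intercept_a:
            raise ValueError("swim_vo2 must exceed the resting intercept")
        if self.j_per_ml_o2 <= 0:
            raise ValueError("j_per_ml_o2 must be positive")


@dataclass(frozen=True)
class CalibrationPoint:
    """One (mean ODBA, V̇O2) observation from respirometry."""

    mean_odba: float
    vo2: float
    setting: str = "treadmill"  # or "enclosure-rest"

    def __post_init__(self) -> None:
        if self.vo2 <= 0:
            raise ValueError("vo2 must be positive")
        if self.mean_odba < 0:
            raise ValueError("mean_odba must be non-negative")


@dataclass(frozen=True)
class CalibrationFit:
    model: CalibrationModel
    r2: float
    p_slope: float
    n: int
    slope_se: float


@dataclass(frozen=True)
class EnergyResult:
    """Deployment-level energetics summary (mass-specific)."""

    total_ee: float       # kJ/kg over the deployment
    daily_ee: float       # kJ kg^-1 day^-1 (FMR_ACC)
    duration_days: float
    swim_fraction: float
    mean_odba: float      # g


def vo2_from_odba(odba, model: CalibrationModel | None = None):
    """Mass-specific oxygen consumption from ODBA via the linear calibration."""
    model = model or CalibrationModel()
    odba = np.asarray(odba, dtype=float)
    if np.any(odba < 0):
        raise ValueError("ODBA must be non-negative")
    out = model.intercept_a + model.slope_b * odba
    return float(out) if out.ndim == 0 else out


def fit_calibration(points) -> CalibrationFit:
    """Ordinary least squares of V̇O2 on mean ODBA over calibration points.

    Returns the fitted line (with the published swim/energy constants
    retained) along with r², the two-sided slope p-value (t, n−2 df) and n.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p.mean_odba for p in pts])
    y = np.array([p.vo2 for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all ODBA values identical")
    res = _sps.linregress(x, y)
    model = CalibrationModel(
        intercept_a=max(res.intercept, 0.0), slope_b=res.slope
    )
    return CalibrationFit(
        model=model,
        r2=res.rvalue ** 2,
        p_slope=res.pvalue,
        n=len(pts),
        slope_se=res.stderr,
    )


def epoch_energy(
    mean_odba: float,
    state: str,
    epoch_length_s: float,
    model: CalibrationModel | None = None,
) -> float:
    """Energy (J per g of bear, == kJ/kg) expended in one single-state epoch."""
    model = model or CalibrationModel()
    if state not in STATES:
        raise ValueError(f"unknown behavior state: {state!r}")
    if epoch_length_s < 0:
        raise ValueError("epoch_length_s must be non-negative")
    vo2 = model.swim_vo2 if state == SWIM else vo2_from_odba(mean_odba, model)
    # ml O2 g^-1 hr^-1 × J/ml × hr = J/g == kJ/kg
    return vo2 * model.j_per_ml_o2 * (epoch_length_s / 3600.0)


def total_and_daily_ee(
    epochs: EpochODBA,
    behavior: BehaviorSeries,
    duration_days: float,
    model: CalibrationModel | None = None,
) -> EnergyResult:
    """Sum behavior-specific epoch energies and divide by deployment days.

    ``epochs`` and ``behavior`` must share a time base (1-s epochs aligned
    with the per-second behavior series).  Gap seconds simply contribute no
    epochs.  The result is mass-specific; multiply by mean body mass for
    absolute kJ/day.
    """
    model = model or CalibrationModel()
    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    if len(epochs) != len(behavior):
        raise ValueError(
            "epoch ODBA and behavior series are not aligned "
            f"({len(epochs)} epochs vs {len(behavior)} seconds)"
        )
    sample_rate = np.max(epochs.n_samples) / epochs.epoch_length_s
    lengths = epochs.n_samples / sample_rate  # partial final epoch shortened
    swim = behavior.state == SWIM
    vo2 = np.where(
        swim,
        model.swim_vo2,
        model.intercept_a + model.slope_b * epochs.mean_odba,
    )
    energies_kj_kg = vo2 * model.j_per_ml_o2 * (lengths / 3600.0)
    total = float(np.sum(energies_kj_kg))
    weights = epochs.n_samples / np.sum(epochs.n_samples)
    return EnergyResult(
        total_ee=total,
        daily_ee=total / duration_days,
        duration_days=duration_days,
        swim_fraction=float(np.mean(swim)),
        mean_odba=float(np.sum(weights * epochs.mean_odba)),
    )
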