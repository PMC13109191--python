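"""CGM series handling: starting glucose, rate of change, trend classes and
windowed glycaemic metrics.

All glucose values are mmol/l internally.  The conventional CGM reporting
range is [2.2, 22.2] mmol/l; values outside it are clipped on construction.
Trend classification uses the standard rate-of-change cut-offs: falling
below -0.05 mmol/l/min, rising above +0.05, stable in between (inclusive on
both ends).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: conventional CGM reporting bounds, mmol/l
GLUCOSE_MIN = 2.2
GLUCOSE_MAX = 22.2

#: level-1 / level-2 hypoglycaemia and hyperglycaemia thresholds, mmol/l
HYPO_L1 = 3.9
HYPO_L2 = 3.0
HYPER_L1 = 10.0
HYPER_L2 = 13.9
TIGHT_UPPER = 7.8

#: glucose trend cut-off, mmol/l per min
TREND_CUTOFF = 0.05

#: molar-mass based conversion factor mmol/l -> mg/dl
MGDL_PER_MMOLL = 18.016


class CgmError(ValueError):
    """Invalid CGM input (unordered/duplicate timestamps, bad windows)."""


@dataclass(frozen=True)
class GlucoseSeries:
    """One participant's timestamped CGM readings.

    Timestamps must be strictly increasing; glucose values are clipped to
    the reporting range on construction.
    """

    participant_id: str
    times: pd.DatetimeIndex
    glucose: np.ndarray

    def __post_init__(self) -> None:
        times = pd.DatetimeIndex(self.times)
        glucose = np.asarray(self.glucose, dtype=float)
        if len(times) != len(glucose):
            raise CgmError("times and glucose must have equal length")
        if len(times) > 1:
            deltas = np.diff(times.asi8)
            if (deltas <= 0).any():
                raise CgmError(
                    f"timestamps must be strictly increasing for participant "
                    f"{self.participant_id}"
                )
        if not np.isfinite(glucose).all():
            raise CgmError("glucose values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "glucose", np.clip(glucose, GLUCOSE_MIN, GLUCOSE_MAX))

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_frame(cls, participant_id: str, frame: pd.DataFrame) -> "GlucoseSeries":
        """Build from a frame with ``timestamp`` and ``glucose_mmol_l`` columns."""
        frame = frame.sort_values("timestamp")
        return cls(
            participant_id=participant_id,
            times=pd.DatetimeIndex(frame["timestamp"]),
            glucose=frame["glucose_mmol_l"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class TrendClass:
    """Glucose trend category with its binary falling indicator."""

    value: str  # falling | stable | rising

    @property
    def binary_falling(self) -> int:
        return int(self.value == "falling")


@dataclass(frozen=True)
class GlycemicMetrics:
    """Standard glycaemic metrics over a window (percentages of readings)."""

    mean: float
    sd: float
    cv: float  # %
    tir_normal: float  # % in [3.9, 10.0]
    tir_tight: float  # % in [3.9, 7.8]
    tbr_l1: float  # % < 3.9
    tbr_l2: float  # % < 3.0
    tar_l1: float  # % > 10.0
    tar_l2: float  # % > 13.9


def starting_glucose(
    series: GlucoseSeries, t: pd.Timestamp, staleness_max: float = 10.0
) -> float | None:
    """Last reading at or before ``t``, no staler than ``staleness_max`` minutes.

    Returns None when no sufficiently fresh reading exists: an absent value,
    not an error.
    """
    idx = series.times.searchsorted(t, side="right") - 1
    if idx < 0:
        return None
    age_min = (t - series.times[idx]).total_seconds() / 60.0
    if age_min > staleness_max:
        return None
    return float(series.glucose[idx])


def _starting_index(
    series: GlucoseSeries, t: pd.Timestamp, staleness_max: float = 10.0
) -> int | None:
    idx = series.times.searchsorted(t, side="right") - 1
    if idx < 0:
        return None
    if (t - series.times[idx]).total_seconds() / 60.0 > staleness_max:
        return None
    return int(idx)


def rate_of_change(
    series: GlucoseSeries,
    t: pd.Timestamp,
    lag: float = 15.0,
    match_tolerance: float = 5.0,
    staleness_max: float = 10.0,
) -> float | None:
    """Glucose rate of change (mmol/l per min) at the reading anchoring ``t``.

    The anchor is the starting-glucose reading at/before ``t``; the
    comparison reading is the one nearest to ``anchor - lag`` within
    ``match_tolerance`` minutes.  The denominator is the actual elapsed time
    between the two readings, not the nominal lag, to avoid bias with
    irregular cadence.
    """
    anchor = _starting_index(series, t, staleness_max)
    if anchor is None:
        return None
    t_anchor = series.times[anchor]
    target = t_anchor - pd.Timedelta(minutes=lag)
    prior_times = series.times[:anchor]
    if len(prior_times) == 0:
        return None
    offsets = np.abs((prior_times - target).total_seconds()) / 60.0
    j = int(np.argmin(offsets))
    if offsets[j] > match_tolerance:
        return None
    dt_min = (t_anchor - prior_times[j]).total_seconds() / 60.0
    if dt_min <= 0:
        return None
    return float((series.glucose[anchor] - series.glucose[j]) / dt_min)


def classify_trend(roc: float) -> TrendClass:
    """Classify a rate of change (mmol/l/min) as falling, stable or rising."""
    if not math.isfinite(roc):
        raise CgmError(f"rate of change must be finite, got {roc!r}")
    if roc < -TREND_CUTOFF:
        return TrendClass("falling")
    if roc > TREND_CUTOFF:
        return TrendClass("rising")
    return TrendClass("stable")


def data_sufficiency(
    series: GlucoseSeries,
    t0: pd.Timestamp,
    t1: pd.Timestamp,
    cgm_interval: float = 5.0,
) -> float:
    """Fraction of expected readings present in the half-open window [t0, t1).

    The denominator is the slot count ``(t1 - t0) / cgm_interval``; the
    fraction is capped at 1.0 for devices that over-sample.  Depends only on
    timestamps, never on glucose values.
    """
    if t1 <= t0:
        raise CgmError("data_sufficiency window must satisfy t1 > t0")
    lo = series.times.searchsorted(t0, side="left")
    hi = series.times.searchsorted(t1, side="left")
    expected = (t1 - t0).total_seconds() / 60.0 / cgm_interval
    return min(1.0, (hi - lo) / expected)


def window_readings(
    series: GlucoseSeries, t0: pd.Timestamp, t1: pd.Timestamp
) -> np.ndarray:
    """Glucose readings with timestamps in [t0, t1)."""
    lo = series.times.searchsorted(t0, side="left")
    hi = series.times.searchsorted(t1, side="left")
    return series.glucose[lo:hi]


def window_metrics(
    series: GlucoseSeries, t0: pd.Timestamp, t1: pd.Timestamp
) -> GlycemicMetrics | None:
    """Standard glycaemic metrics over [t0, t1); None with fewer than 2 readings.

    Time-in-range percentages are reading-count fractions, so
    tbr_l1 + tir_normal + tar_l1 = 100 exactly before rounding.
    """
    g = window_readings(series, t0, t1)
    if len(g) < 2:
        return None
    n = len(g)
    mean = float(np.mean(g))
    sd = float(np.std(g, ddof=1))
    pct = lambda mask: 100.0 * float(np.count_nonzero(mask)) / n  # noqa: E731
    return GlycemicMetrics(
        mean=mean,
        sd=sd,
        cv=100.0 * sd / mean,
        tir_normal=pct((g >= HYPO_L1) & (g <= HYPER_L1)),
        tir_tight=pct((g >= HYPO_L1) & (g <= TIGHT_UPPER)),
        tbr_l1=pct(g < HYPO_L1),
        tbr_l2=pct(g < HYPO_L2),
        tar_l1=pct(g > HYPER_L1),
        tar_l2=pct(g > HYPER_L2),
    )


def mmol_to_mgdl(g: float) -> float:
    """Convert mmol/l to mg/dl (factor 18.016, from glucose molar mass 180.16)."""
    if g < 0:
        raise CgmError("glucose cannot be negative")
    return g * MGDL_PER_MMOLL


def mmol_to_mgdl_display(g: float) -> int:
    """mg/dl equivalent rounded to the nearest integer, as usually displayed."""
    return int(round(mmol_to_mgdl(g)))


def read_cgm_csv(path) -> dict[str, GlucoseSeries]:
    """Read a ``cgm.csv`` (participant_id, timestamp, glucose_mmol_l) into series."""
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    return {
        str(pid): GlucoseSeries.from_frame(str(pid), grp)
        for pid, grp in frame.groupby("participant_id", sort=True)
    }
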