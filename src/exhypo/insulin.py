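"""Insulin on board (IOB) with linear decay and time-since-bolus categories.

IOB follows the linear degradation model: a bolus of ``u`` units delivered
``dt`` minutes ago contributes ``u * (1 - dt/dia)`` while ``0 <= dt < dia``
and nothing afterwards.  The duration of insulin action (DIA) defaults to
4 h (240 min).  Only logged boluses enter IOB; basal delivery and temporary
basal changes are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_DIA_MIN = 240.0

#: time-since-last-bolus category edges, minutes
BOLUS_CAT_EDGE_LOW = 90.0  # 1.5 h
BOLUS_CAT_EDGE_HIGH = 210.0  # 3.5 h

BOLUS_CATEGORIES = ("lt_1p5h", "h1p5_to_3p5", "gt_3p5h", "none")


@dataclass(frozen=True)
class BolusEvent:
    participant_id: str
    timestamp: pd.Timestamp
    units: float

    def __post_init__(self) -> None:
        if not self.units > 0:
            raise ValueError(f"bolus units must be positive, got {self.units}")
        if pd.isna(self.timestamp):
            raise ValueError("bolus timestamp must be finite")


@dataclass(frozen=True)
class IobResult:
    """IOB snapshot at a time point."""

    iob: float
    iob_per_kg: float | None  # None when body weight is unknown
    minutes_since_last_bolus: float | None
    bolus_category: str


def iob_at(
    boluses: Iterable[BolusEvent], t: pd.Timestamp, dia: float = DEFAULT_DIA_MIN
) -> float:
    """Active insulin (units) at time ``t`` under linear decay."""
    if dia <= 0:
        raise ValueError("duration of insulin action must be positive")
    total = 0.0
    for b in boluses:
        dt = (t - b.timestamp).total_seconds() / 60.0
        if 0 <= dt < dia:
            total += b.units * (1.0 - dt / dia)
    return total


def iob_series(
    boluses: Sequence[BolusEvent],
    t0: pd.Timestamp,
    t1: pd.Timestamp,
    dia: float = DEFAULT_DIA_MIN,
) -> pd.Series:
    """IOB evaluated at every integer minute in [t0, t1)."""
    if t1 <= t0:
        raise ValueError("window must satisfy t1 > t0")
    minutes = pd.date_range(t0, t1, freq="1min", inclusive="left")
    if not boluses:
        return pd.Series(np.zeros(len(minutes)), index=minutes, name="iob")
    bolus_t = np.array([b.timestamp.value for b in boluses], dtype="int64")
    units = np.array([b.units for b in boluses], dtype=float)
    dt_min = (minutes.asi8[:, None] - bolus_t[None, :]) / 60e9
    active = (dt_min >= 0) & (dt_min < dia)
    contrib = units[None, :] * (1.0 - dt_min / dia) * active
    return pd.Series(contrib.sum(axis=1), index=minutes, name="iob")


def minutes_since_last_bolus(
    boluses: Iterable[BolusEvent], t: pd.Timestamp
) -> float | None:
    """Minutes from the latest bolus at or before ``t``; None if there is none."""
    past = [
        (t - b.timestamp).total_seconds() / 60.0
        for b in boluses
        if b.timestamp <= t
    ]
    return min(past) if past else None


def bolus_category(boluses: Iterable[BolusEvent], t: pd.Timestamp) -> str:
    """Time-since-last-bolus category: <1.5 h, 1.5–3.5 h, >3.5 h, or none.

    The middle band is closed on both sides ([90, 210] min).
    """
    m = minutes_since_last_bolus(boluses, t)
    if m is None:
        return "none"
    if m < BOLUS_CAT_EDGE_LOW:
        return "lt_1p5h"
    if m <= BOLUS_CAT_EDGE_HIGH:
        return "h1p5_to_3p5"
    return "gt_3p5h"


def iob_result(
    boluses: Sequence[BolusEvent],
    t: pd.Timestamp,
    weight_kg: float | None,
    dia: float = DEFAULT_DIA_MIN,
) -> IobResult:
    """IOB, IOB/kg and bolus-timing category at ``t``.

    IOB/kg is absent (None) when body weight is unknown; downstream
    imputation fills it.
    """
    iob = iob_at(boluses, t, dia)
    per_kg = None
    if weight_kg is not None and np.isfinite(weight_kg) and weight_kg > 0:
        per_kg = iob / weight_kg
    return IobResult(
        iob=iob,
        iob_per_kg=per_kg,
        minutes_since_last_bolus=minutes_since_last_bolus(boluses, t),
        bolus_category=bolus_category(boluses, t),
    )


def read_bolus_csv(path) -> dict[str, list[BolusEvent]]:
    """Read a ``bolus.csv`` (participant_id, timestamp, units) into event lists."""
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    out: dict[str, list[BolusEvent]] = {}
    for pid, grp in frame.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        out[str(pid)] = [
            BolusEvent(str(pid), row.timestamp, float(row.units))
            for row in grp.itertuples()
        ]
    return out
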