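"""Exercise bouts: data model, deduplication/overlap handling, inclusion
criteria and hypoglycaemia outcome labelling.

A bout occupies the half-open interval [start, start + duration): a reading
exactly at the end belongs to the next interval, and two bouts that merely
touch do not overlap.  Inclusion requires a 10–120 min duration, >=60% CGM
data sufficiency during the bout and >=40% in the hour before, and a
volitional-exercise flag.  The outcome is level-1 hypoglycaemia: any CGM
reading strictly below 3.9 mmol/l during the bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgm import HYPO_L1, GlucoseSeries, data_sufficiency, window_readings

DURATION_MIN = 10.0
DURATION_MAX = 120.0
SUFFICIENCY_DURING = 0.60
SUFFICIENCY_PRIOR = 0.40

EXCLUSION_REASONS = (
    "bad_timestamp",
    "duplicate_or_overlap",
    "duration_out_of_range",
    "insufficient_cgm_during",
    "insufficient_cgm_prior",
    "non_volitional",
)


@dataclass(frozen=True)
class ExerciseBout:
    participant_id: str
    bout_id: str
    start: pd.Timestamp  # NaT marks an unparseable logged time
    duration_min: float
    exercise_label: str = ""
    intensity_raw: object = None  # category string or Borg integer
    intensity_scale: str = "category"  # category | borg
    volitional: bool = True

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(minutes=self.duration_min)


@dataclass(frozen=True)
class BoutQC:
    """Inclusion verdict; a bout is included iff no exclusion reasons apply."""

    bout_id: str
    reasons: tuple[str, ...] = field(default=())

    @property
    def included(self) -> bool:
        return not self.reasons


@dataclass(frozen=True)
class BoutOutcome:
    bout_id: str
    hypo: bool
    min_glucose_during: float


def _overlaps(a: ExerciseBout, b: ExerciseBout) -> bool:
    return a.start < b.end and b.start < a.end


def dedupe_and_overlaps(
    bouts: list[ExerciseBout],
) -> tuple[list[ExerciseBout], list[ExerciseBout]]:
    """Collapse exact duplicates; drop both members of partial overlaps.

    Exact duplicates (same start and duration) keep one record and exclude
    the rest.  For non-identical overlapping pairs there is no principled
    survivor, so both are excluded — conservative, symmetric and
    order-independent.  Returns (kept, excluded).
    """
    bouts = sorted(
        [b for b in bouts if not pd.isna(b.start)], key=lambda b: (b.start, b.duration_min)
    )
    excluded: list[ExerciseBout] = []
    # collapse exact duplicates first
    uniques: list[ExerciseBout] = []
    seen: set[tuple] = set()
    for b in bouts:
        key = (b.start, b.duration_min)
        if key in seen:
            excluded.append(b)
        else:
            seen.add(key)
            uniques.append(b)
    # flag every member of any partially overlapping pair
    bad = set()
    for i, a in enumerate(uniques):
        for b in uniques[i + 1 :]:
            if b.start >= a.end:
                break
            if _overlaps(a, b):
                bad.add(a.bout_id)
                bad.add(b.bout_id)
    kept = [b for b in uniques if b.bout_id not in bad]
    excluded.extend(b for b in uniques if b.bout_id in bad)
    return kept, excluded


def apply_inclusion(
    bout: ExerciseBout,
    series: GlucoseSeries | None,
    overlap_excluded: bool = False,
) -> BoutQC:
    """Evaluate all inclusion criteria; failing reasons accumulate."""
    if pd.isna(bout.start):
        return BoutQC(bout.bout_id, ("bad_timestamp",))
    reasons: list[str] = []
    if overlap_excluded:
        reasons.append("duplicate_or_overlap")
    if not (DURATION_MIN <= bout.duration_min <= DURATION_MAX):
        reasons.append("duration_out_of_range")
    if series is None:
        reasons.extend(["insufficient_cgm_during", "insufficient_cgm_prior"])
    else:
        if data_sufficiency(series, bout.start, bout.end) < SUFFICIENCY_DURING:
            reasons.append("insufficient_cgm_during")
        prior_start = bout.start - pd.Timedelta(minutes=60)
        if data_sufficiency(series, prior_start, bout.start) < SUFFICIENCY_PRIOR:
            reasons.append("insufficient_cgm_prior")
    if not bout.volitional:
        reasons.append("non_volitional")
    return BoutQC(bout.bout_id, tuple(reasons))


def label_outcome(bout: ExerciseBout, series: GlucoseSeries) -> BoutOutcome:
    """Level-1 hypoglycaemia label: any reading < 3.9 mmol/l in [start, end)."""
    g = window_readings(series, bout.start, bout.end)
    if len(g) == 0:
        raise ValueError(
            f"no CGM readings during bout {bout.bout_id}; run QC before labelling"
        )
    mn = float(np.min(g))
    return BoutOutcome(bout.bout_id, hypo=mn < HYPO_L1, min_glucose_during=mn)


def qc_participant(
    bouts: list[ExerciseBout], series: GlucoseSeries | None
) -> dict[str, BoutQC]:
    """Full QC for one participant: dedup/overlap pass, then inclusion criteria."""
    parseable = [b for b in bouts if not pd.isna(b.start)]
    _, overlap_excluded = dedupe_and_overlaps(parseable)
    overlap_ids = {b.bout_id for b in overlap_excluded}
    out: dict[str, BoutQC] = {}
    for b in bouts:
        out[b.bout_id] = apply_inclusion(
            b, series, overlap_excluded=b.bout_id in overlap_ids
        )
    return out


def qc_report(qcs: dict[str, BoutQC]) -> pd.DataFrame:
    """Tidy per-bout QC table (bout_id, included, semicolon-joined reasons)."""
    return pd.DataFrame(
        {
            "bout_id": list(qcs),
            "included": [qc.included for qc in qcs.values()],
            "reasons": [";".join(qc.reasons) for qc in qcs.values()],
        }
    )


def read_bouts_csv(path) -> dict[str, list[ExerciseBout]]:
    """Read a ``bouts.csv``; unparseable start timestamps become NaT and are
    later excluded with reason ``bad_timestamp``."""
    frame = pd.read_csv(path, dtype={"participant_id": str})
    starts = pd.to_datetime(frame["start_timestamp"], errors="coerce", format="ISO8601")
    out: dict[str, list[ExerciseBout]] = {}
    for i, row in enumerate(frame.itertuples()):
        pid = str(row.participant_id)
        bout_id = str(getattr(row, "bout_id", f"{pid}_b{i}"))
        raw = row.intensity_raw
        scale = getattr(row, "intensity_scale", "category")
        if scale == "borg":
            try:
                raw = int(raw)
            except (TypeError, ValueError):
                raw = None
        volitional = bool(getattr(row, "volitional", True))
        out.setdefault(pid, []).append(
            ExerciseBout(
                participant_id=pid,
                bout_id=bout_id,
                start=starts.iloc[i],
                duration_min=float(row.duration_min),
                exercise_label=str(row.exercise_label),
                intensity_raw=raw,
                intensity_scale=str(scale),
                volitional=volitional,
            )
        )
    return out
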