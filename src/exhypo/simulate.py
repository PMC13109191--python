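"""Synthetic cohorts with a known hypoglycaemia-generating process.

Each participant's interstitial glucose is a mean-reverting AR(1) process
around an individual baseline, sampled at the CGM cadence.  During an
exercise bout the process acquires a downward drift composed of a base
exercise drop rate, an insulin-on-board term proportional to IOB/kg at the
bout start, and a carry-over of the pre-bout glucose trend; the whole drift
scales with reported intensity (light/moderate/vigorous = 0.5/1.0/1.5).
Bolus doses are placed at three jittered mealtimes per day plus occasional
corrections.  CGM readings are deleted in contiguous geometric runs to
emulate sensor dropouts.

Because the drift per bout is recorded, the per-bout *true* conditional
hypoglycaemia probability can be recomputed by Monte Carlo
(:func:`true_risk`), giving downstream calibration checks a perfectly
calibrated oracle score.

The generator emits the pipeline's input CSV dialects and is byte-stable
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bouts import ExerciseBout
from .cgm import GLUCOSE_MAX, GLUCOSE_MIN, HYPO_L1, GlucoseSeries
from .insulin import BolusEvent

INTENSITY_FACTORS = {"light": 0.5, "moderate": 1.0, "vigorous": 1.5}

_AEROBIC_LABELS = ["running", "cycling", "walking", "swimming"]
_ANAEROBIC_LABELS = ["weightlifting", "resistance training", "sprinting"]
_MIXED_LABELS = ["circuit training", "football", "tennis"]

_START_DATE = pd.Timestamp("2023-03-01 00:00:00")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings.

    Defaults describe a free-living study: a month of 5-min CGM, ~3.5
    boluses/day, 10–120 min bouts, and a marginal bout-level hypoglycaemia
    rate of roughly one bout in ten.
    """

    n_participants: int = 250
    bouts_per_participant_range: tuple[int, int] = (12, 30)
    days: int = 28
    cgm_interval: int = 5  # minutes
    baseline_glucose_mean_range: tuple[float, float] = (7.5, 11.0)  # mmol/l
    ar1_coefficient: float = 0.98
    noise_sd: float = 0.45  # mmol/l per step
    bolus_rate_per_day: float = 3.5
    bolus_units_range: tuple[float, float] = (2.0, 8.0)
    exercise_drop_rate_per_10min: float = 0.35  # mmol/l per 10 min, base
    iob_drop_multiplier: float = 2.0  # mmol/l per 10 min per (unit/kg)
    trend_carryover: float = 0.6
    missingness_fraction: float = 0.08
    seed: int = 0
    inject_qc_failures: bool = True

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise SimulationError("n_participants must be positive")
        lo, hi = self.bouts_per_participant_range
        if not (0 < lo <= hi):
            raise SimulationError("bouts_per_participant_range must be nonempty")
        if self.days <= 0:
            raise SimulationError("days must be positive")
        if 60 % self.cgm_interval != 0:
            raise SimulationError("cgm_interval must divide 60")
        if not 0 <= self.missingness_fraction < 1:
            raise SimulationError("missingness_fraction must be in [0, 1)")
        if not 0 <= self.ar1_coefficient < 1:
            raise SimulationError("ar1_coefficient must be in [0, 1)")
        b_lo, b_hi = self.baseline_glucose_mean_range
        if not b_lo <= b_hi:
            raise SimulationError("baseline_glucose_mean_range must be nonempty")
        u_lo, u_hi = self.bolus_units_range
        if not 0 < u_lo <= u_hi:
            raise SimulationError("bolus_units_range must be nonempty and positive")


@dataclass
class SimCohort:
    """A generated cohort plus the latent truth behind each bout."""

    config: SimConfig
    participants: pd.DataFrame
    series: dict[str, GlucoseSeries]
    boluses: dict[str, list[BolusEvent]]
    bouts: dict[str, list[ExerciseBout]]
    truth: pd.DataFrame
    #: expected per-reason exclusion counts for the injected QC violations
    qc_manifest: dict[str, int] = field(default_factory=dict)
    #: per-bout latent state needed by true_risk (kept in memory only)
    _latent: dict[str, dict] = field(default_factory=dict, repr=False)

    def all_bouts(self) -> list[ExerciseBout]:
        return [b for pid in sorted(self.bouts) for b in self.bouts[pid]]


def _simulate_participants(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    sex = np.where(rng.random(n) < 0.61, "F", "M")
    age = np.clip(np.exp(rng.normal(np.log(27.0), 0.45, n)), 12.0, 80.0)
    bmi = np.clip(rng.normal(24.0, 3.0, n), 17.0, 38.0)
    height = np.clip(rng.normal(1.70, 0.09, n), 1.45, 2.00)
    weight = bmi * height**2
    hba1c = np.clip(rng.normal(51.0, 8.0, n), 30.0, 100.0)
    ysd = np.clip(rng.gamma(2.0, 7.0, n), 0.5, np.maximum(age - 1.0, 0.5))
    modality = rng.choice(["MDI", "pump", "closed_loop"], size=n, p=[0.24, 0.33, 0.43])
    scale = rng.choice(["category", "borg"], size=n, p=[0.8, 0.2])
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age_years": np.round(age, 1),
            "sex": sex,
            "bmi": np.round(bmi, 1),
            "weight_kg": np.round(weight, 1),
            "hba1c_mmol_mol": np.round(hba1c, 1),
            "years_since_diagnosis": np.round(ysd, 1),
            "insulin_modality": modality,
            "intensity_scale": scale,
        }
    )


def _simulate_boluses(
    cfg: SimConfig, rng: np.random.Generator, pid: str
) -> list[BolusEvent]:
    events = []
    u_lo, u_hi = cfg.bolus_units_range
    corrections_per_day = max(0.0, cfg.bolus_rate_per_day - 3.0)
    for day in range(cfg.days):
        base = _START_DATE + pd.Timedelta(days=day)
        for meal_min in (7 * 60 + 30, 12 * 60 + 30, 18 * 60 + 30):
            jitter = rng.normal(0.0, 40.0)
            t = base + pd.Timedelta(minutes=float(np.round(meal_min + jitter)))
            events.append(BolusEvent(pid, t, float(np.round(rng.uniform(u_lo, u_hi), 2))))
        for _ in range(rng.poisson(corrections_per_day)):
            t = base + pd.Timedelta(minutes=float(rng.integers(6 * 60, 23 * 60)))
            events.append(
                BolusEvent(pid, t, float(np.round(rng.uniform(u_lo, u_hi / 2), 2)))
            )
    events.sort(key=lambda e: e.timestamp)
    return events


def _iob_per_kg(boluses: list[BolusEvent], t: pd.Timestamp, weight: float) -> float:
    total = 0.0
    for b in boluses:
        dt = (t - b.timestamp).total_seconds() / 60.0
        if 0 <= dt < 240.0:
            total += b.units * (1.0 - dt / 240.0)
    return total / weight


def _place_bouts(
    cfg: SimConfig, rng: np.random.Generator, pid: str, intensity_scale: str
) -> list[dict]:
    """Non-overlapping bout records with label, intensity and duration."""
    target = int(rng.integers(*cfg.bouts_per_participant_range, endpoint=True))
    placed: list[dict] = []
    tries = 0
    while len(placed) < target and tries < target * 30:
        tries += 1
        day = int(rng.integers(0, cfg.days))
        start_min = int(rng.integers(6 * 60, 21 * 60))
        start = _START_DATE + pd.Timedelta(days=day, minutes=start_min)
        duration = float(np.clip(np.round(np.exp(rng.normal(np.log(30.0), 0.5))), 10, 118))
        end = start + pd.Timedelta(minutes=duration)
        buffer = pd.Timedelta(minutes=20)
        if any(
            (start < p["end"] + buffer) and (p["start"] < end + buffer) for p in placed
        ):
            continue
        level = rng.choice(["light", "moderate", "vigorous"], p=[0.43, 0.43, 0.14])
        kind = rng.choice(["aerobic", "anaerobic", "mixed"], p=[0.65, 0.11, 0.24])
        label = rng.choice(
            {"aerobic": _AEROBIC_LABELS, "anaerobic": _ANAEROBIC_LABELS, "mixed": _MIXED_LABELS}[kind]
        )
        if intensity_scale == "borg":
            raw = int(
                rng.integers(*{"light": (7, 12), "moderate": (12, 15), "vigorous": (15, 19)}[level])
            )
        else:
            raw = level
        placed.append(
            {
                "start": start,
                "end": end,
                "duration": duration,
                "level": level,
                "label": str(label),
                "raw": raw,
            }
        )
    placed.sort(key=lambda p: p["start"])
    return placed


def _geometric_run_mask(
    rng: np.random.Generator, n: int, fraction: float, mean_run: float = 6.0
) -> np.ndarray:
    """Boolean deletion mask with ~``fraction`` of slots removed in runs."""
    drop = np.zeros(n, dtype=bool)
    if fraction <= 0:
        return drop
    target = int(round(fraction * n))
    while drop.sum() < target:
        start = int(rng.integers(0, n))
        run = int(rng.geometric(1.0 / mean_run))
        drop[start : start + run] = True
    return drop


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full cohort; identical config and seed give identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    participants = _simulate_participants(cfg, rng)

    steps_per_day = 24 * 60 // cfg.cgm_interval
    n_steps = cfg.days * steps_per_day
    grid = _START_DATE + pd.to_timedelta(
        np.arange(n_steps) * cfg.cgm_interval, unit="m"
    )
    steps_per_10min = 10.0 / cfg.cgm_interval

    series: dict[str, GlucoseSeries] = {}
    boluses: dict[str, list[BolusEvent]] = {}
    bouts: dict[str, list[ExerciseBout]] = {}
    truth_rows: list[dict] = []
    latent: dict[str, dict] = {}

    for p_idx in range(cfg.n_participants):
        prow = participants.iloc[p_idx]
        pid = prow["participant_id"]
        baseline = rng.uniform(*cfg.baseline_glucose_mean_range)
        p_boluses = _simulate_boluses(cfg, rng, pid)
        placed = _place_bouts(cfg, rng, pid, prow["intensity_scale"])

        # per-step drift (mmol/l, negative = drop) excluding trend carry-over
        drift = np.zeros(n_steps)
        bout_meta = []
        for k, p in enumerate(placed):
            s0 = int(np.searchsorted(grid, p["start"], side="left"))
            s1 = int(np.searchsorted(grid, p["end"], side="left"))
            s1 = max(s1, s0 + 1)
            iobkg = _iob_per_kg(p_boluses, p["start"], float(prow["weight_kg"]))
            factor = INTENSITY_FACTORS[p["level"]]
            drop_per_10min = (
                cfg.exercise_drop_rate_per_10min + cfg.iob_drop_multiplier * iobkg
            ) * factor
            drop_per_step = drop_per_10min / steps_per_10min
            drift[s0:s1] -= drop_per_step
            bout_meta.append(
                {
                    "bout_id": f"{pid}_b{k:03d}",
                    "s0": s0,
                    "s1": s1,
                    "iobkg": iobkg,
                    "drop_per_10min": drop_per_10min,
                    "drop_per_step": drop_per_step,
                    "factor": factor,
                    **p,
                }
            )

        # AR(1) forward simulation with trend carry-over inside bouts
        eps = rng.normal(0.0, cfg.noise_sd, n_steps)
        g = np.empty(n_steps)
        sd_stat = cfg.noise_sd / np.sqrt(1.0 - cfg.ar1_coefficient**2)
        g[0] = baseline + rng.normal(0.0, sd_stat)
        carry = np.zeros(n_steps)
        starts = {m["s0"]: m for m in bout_meta}
        carry_active = 0.0
        carry_until = -1
        phi = cfg.ar1_coefficient
        lag_steps = max(1, int(round(15.0 / cfg.cgm_interval)))
        for i in range(1, n_steps):
            if i in starts:
                m = starts[i]
                if i - 1 - lag_steps >= 0:
                    roc = (g[i - 1] - g[i - 1 - lag_steps]) / (lag_steps * cfg.cgm_interval)
                else:
                    roc = 0.0
                carry_active = cfg.trend_carryover * roc * cfg.cgm_interval
                carry_until = m["s1"]
                m["carry_per_step"] = carry_active
                m["pre_state"] = g[i - 1]
            if i >= carry_until:
                carry_active = 0.0
            carry[i] = carry_active
            g[i] = baseline + phi * (g[i - 1] - baseline) + eps[i] + drift[i] + carry[i]

        # missingness in geometric runs
        drop_mask = _geometric_run_mask(rng, n_steps, cfg.missingness_fraction)
        keep = ~drop_mask
        observed = np.clip(g[keep], GLUCOSE_MIN, GLUCOSE_MAX)
        series[pid] = GlucoseSeries(pid, pd.DatetimeIndex(grid[keep]), observed)
        boluses[pid] = p_boluses

        p_bouts = []
        for m in bout_meta:
            if "pre_state" not in m:  # bout started at step 0
                m["pre_state"] = g[max(m["s0"] - 1, 0)]
                m["carry_per_step"] = 0.0
            bout = ExerciseBout(
                participant_id=pid,
                bout_id=m["bout_id"],
                start=m["start"],
                duration_min=m["duration"],
                exercise_label=m["label"],
                intensity_raw=m["raw"],
                intensity_scale=prow["intensity_scale"],
                volitional=True,
            )
            p_bouts.append(bout)
            truth_rows.append(
                {
                    "bout_id": m["bout_id"],
                    "participant_id": pid,
                    "drop_per_10min": m["drop_per_10min"],
                    "iob_per_kg_start": m["iobkg"],
                    "intensity_factor": m["factor"],
                    "carry_per_step": m["carry_per_step"],
                    "pre_state": m["pre_state"],
                    "n_slots": m["s1"] - m["s0"],
                }
            )
            latent[m["bout_id"]] = {
                "baseline": baseline,
                "pre_state": m["pre_state"],
                "drop_per_step": m["drop_per_step"],
                "carry_per_step": m["carry_per_step"],
                "kept": keep[m["s0"] : m["s1"]].copy(),
            }
        bouts[pid] = p_bouts

    cohort = SimCohort(
        config=cfg,
        participants=participants,
        series=series,
        boluses=boluses,
        bouts=bouts,
        truth=pd.DataFrame(truth_rows),
        _latent=latent,
    )
    if cfg.inject_qc_failures:
        _inject_qc_failures(cohort)
    return cohort


def _inject_qc_failures(cohort: SimCohort) -> None:
    """Append one engineered violation per exclusion reason.

    The expected per-reason excluded counts are recorded in
    ``cohort.qc_manifest``; they are exact when ``missingness_fraction`` is
    zero (random dropouts can add further sufficiency exclusions).
    """
    pid = cohort.participants["participant_id"].iloc[0]
    host = cohort.bouts[pid]
    base = [b for b in host if not pd.isna(b.start)]
    anchor = base[0]

    def mk(bout_id, start, duration, volitional=True):
        return ExerciseBout(
            participant_id=pid,
            bout_id=bout_id,
            start=start,
            duration_min=duration,
            exercise_label="running",
            intensity_raw="moderate" if anchor.intensity_scale == "category" else 13,
            intensity_scale=anchor.intensity_scale,
            volitional=volitional,
        )

    injected = []
    # bad timestamp (written to CSV as unparseable text)
    injected.append(mk("QC_bad_ts", pd.NaT, 30.0))
    # exact duplicate of an existing bout -> one excluded
    injected.append(mk("QC_dup", anchor.start, anchor.duration_min))
    # partial overlap with another existing bout -> both excluded
    victim = base[1] if len(base) > 1 else base[0]
    injected.append(
        mk("QC_overlap", victim.start + pd.Timedelta(minutes=5), victim.duration_min)
    )
    # duration violations, placed in quiet early-morning slots on distinct days
    day = pd.Timedelta(days=1)
    injected.append(mk("QC_short", _START_DATE + day + pd.Timedelta(hours=3), 5.0))
    injected.append(
        mk("QC_long", _START_DATE + 2 * day + pd.Timedelta(hours=2), 150.0)
    )
    # insufficient CGM during: delete every reading inside this window
    t_during = _START_DATE + 3 * day + pd.Timedelta(hours=3)
    injected.append(mk("QC_during", t_during, 30.0))
    s = cohort.series[pid]
    in_win = np.asarray(
        (s.times >= t_during) & (s.times < t_during + pd.Timedelta(minutes=30))
    )
    cohort.series[pid] = GlucoseSeries(pid, s.times[~in_win], s.glucose[~in_win])
    # insufficient CGM in the prior hour: bout 15 min after record start
    injected.append(mk("QC_prior", _START_DATE + pd.Timedelta(minutes=15), 30.0))
    # non-volitional activity
    injected.append(
        mk("QC_nonvol", _START_DATE + 4 * day + pd.Timedelta(hours=3), 30.0, volitional=False)
    )
    host.extend(injected)
    cohort.qc_manifest = {
        "bad_timestamp": 1,
        "duplicate_or_overlap": 3,  # duplicate + both members of the overlap pair
        "duration_out_of_range": 2,
        "insufficient_cgm_during": 1,
        "insufficient_cgm_prior": 1,
        "non_volitional": 1,
    }


def true_risk(
    cohort: SimCohort, n_rep: int = 400, seed: int = 12345
) -> pd.DataFrame:
    """Monte-Carlo conditional hypoglycaemia probability for every generated bout.

    For each bout the in-bout AR(1)-with-drift process is re-simulated
    ``n_rep`` times from the recorded pre-bout latent state, the bout's
    actual missing-reading pattern is applied, and the fraction of paths
    with an observed reading < 3.9 mmol/l is returned.  The generated label
    is, conditional on that state, a Bernoulli draw with this probability.
    """
    rng = np.random.default_rng(seed)
    cfg = cohort.config
    phi = cfg.ar1_coefficient
    rows = []
    for bout_id, lat in cohort._latent.items():
        kept = lat["kept"]
        n_slots = len(kept)
        if n_slots == 0 or not kept.any():
            rows.append({"bout_id": bout_id, "true_risk": np.nan})
            continue
        g = np.full(n_rep, lat["pre_state"])
        delta = -lat["drop_per_step"] + lat["carry_per_step"]
        hit = np.zeros(n_rep, dtype=bool)
        for j in range(n_slots):
            g = (
                lat["baseline"]
                + phi * (g - lat["baseline"])
                + rng.normal(0.0, cfg.noise_sd, n_rep)
                + delta
            )
            if kept[j]:
                hit |= g < HYPO_L1
        rows.append({"bout_id": bout_id, "true_risk": float(hit.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV output


def _fmt(x: float, nd: int = 4) -> str:
    return f"{x:.{nd}f}"


def write_cohort(cohort: SimCohort, directory) -> dict[str, Path]:
    """Write the cohort in the pipeline's input CSV dialects.

    Output is byte-identical for identical cohorts: floats use fixed
    formats and rows follow generation order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    cgm_rows = []
    for pid in sorted(cohort.series):
        s = cohort.series[pid]
        for t, gval in zip(s.times, s.glucose):
            cgm_rows.append(f"{pid},{t.isoformat()},{_fmt(gval, 2)}")
    paths["cgm"] = directory / "cgm.csv"
    paths["cgm"].write_text(
        "participant_id,timestamp,glucose_mmol_l\n" + "\n".join(cgm_rows) + "\n"
    )

    bolus_rows = [
        f"{pid},{b.timestamp.isoformat()},{_fmt(b.units, 2)}"
        for pid in sorted(cohort.boluses)
        for b in cohort.boluses[pid]
    ]
    paths["bolus"] = directory / "bolus.csv"
    paths["bolus"].write_text(
        "participant_id,timestamp,units\n" + "\n".join(bolus_rows) + "\n"
    )

    bout_rows = []
    for pid in sorted(cohort.bouts):
        for b in cohort.bouts[pid]:
            start = "not a timestamp" if pd.isna(b.start) else b.start.isoformat()
            bout_rows.append(
                f"{pid},{b.bout_id},{start},{_fmt(b.duration_min, 1)},"
                f"{b.exercise_label},{b.intensity_raw},{b.intensity_scale},"
                f"{str(b.volitional)}"
            )
    paths["bouts"] = directory / "bouts.csv"
    paths["bouts"].write_text(
        "participant_id,bout_id,start_timestamp,duration_min,exercise_label,"
        "intensity_raw,intensity_scale,volitional\n" + "\n".join(bout_rows) + "\n"
    )

    pcols = [
        "participant_id",
        "age_years",
        "sex",
        "bmi",
        "weight_kg",
        "hba1c_mmol_mol",
        "years_since_diagnosis",
        "insulin_modality",
    ]
    paths["participants"] = directory / "participants.csv"
    cohort.participants[pcols].to_csv(
        paths["participants"], index=False, float_format="%.1f"
    )

    paths["truth"] = directory / "truth.csv"
    cohort.truth.to_csv(paths["truth"], index=False, float_format="%.6f")
    return paths


def load_cohort_dir(directory):
    """Read a written cohort directory back into pipeline inputs."""
    from .bouts import read_bouts_csv
    from .cgm import read_cgm_csv
    from .features import read_participants_csv
    from .insulin import read_bolus_csv

    directory = Path(directory)
    return {
        "participants": read_participants_csv(directory / "participants.csv"),
        "series": read_cgm_csv(directory / "cgm.csv"),
        "boluses": read_bolus_csv(directory / "bolus.csv"),
        "bouts": read_bouts_csv(directory / "bouts.csv"),
    }
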