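"""Per-bout predictor table: candidate variables readily available at the
start of exercise, extended pre-exercise-hour CGM metrics, category
mappings, and k-nearest-neighbour imputation of missing values.

The table keeps categoricals in raw form (``trend``, ``time_of_day``, ...)
so imputation can vote over categories; :func:`dummy_expand` then adds the
indicator columns the boosted model consumes.  No reference level is
dropped — tree models are indifferent to the redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bouts as bouts_mod
from . import cgm, insulin

# ---------------------------------------------------------------------------
# column dictionary

#: continuous candidate predictors
CONTINUOUS_FEATURES = [
    "starting_glucose",
    "duration_min",
    "roc",
    "iob_per_kg",
    "age_years",
    "bmi",
    "hba1c_mmol_mol",
    "years_since_diagnosis",
]

#: pre-exercise-hour CGM metrics (extended set)
PRIOR_HOUR_FEATURES = [
    "prior_mean",
    "prior_sd",
    "prior_cv",
    "prior_tir_normal",
    "prior_tir_tight",
    "prior_tbr_l1",
    "prior_tbr_l2",
    "prior_tar_l1",
    "prior_tar_l2",
]

#: raw categorical predictors and their levels
CATEGORICAL_LEVELS = {
    "trend": ["falling", "stable", "rising"],
    "time_of_day": ["morning", "afternoon", "evening"],
    "intensity": ["light", "moderate", "vigorous"],
    "exercise_type": ["aerobic", "anaerobic", "mixed"],
    "bolus_category": ["lt_1p5h", "h1p5_to_3p5", "gt_3p5h", "none"],
    "sex": ["F", "M"],
    "insulin_modality": ["MDI", "pump", "closed_loop"],
}
CATEGORICAL_FEATURES = list(CATEGORICAL_LEVELS)

#: indicator columns produced by dummy_expand (no reference level dropped)
DUMMY_COLUMNS = {
    "trend": {"falling": "roc_falling", "stable": "roc_stable", "rising": "roc_rising"},
    "time_of_day": {
        "morning": "tod_morning",
        "afternoon": "tod_afternoon",
        "evening": "tod_evening",
    },
    "exercise_type": {
        "aerobic": "type_aerobic",
        "anaerobic": "type_anaerobic",
        "mixed": "type_mixed",
    },
    "bolus_category": {
        "lt_1p5h": "bolus_lt_1p5h",
        "h1p5_to_3p5": "bolus_1p5_to_3p5h",
        "gt_3p5h": "bolus_gt_3p5h",
        "none": "bolus_none",
    },
    "insulin_modality": {
        "MDI": "modality_mdi",
        "pump": "modality_pump",
        "closed_loop": "modality_closed_loop",
    },
    "sex": {"F": "sex_female"},  # binary: one indicator suffices
}

#: candidate pool for forward selection — the readily-available variables,
#: dummy-expanded, plus intensity as an ordinal
CANDIDATE_FEATURES = [
    "starting_glucose",
    "duration_min",
    "roc_falling",
    "roc_stable",
    "roc_rising",
    "bolus_gt_3p5h",
    "bolus_lt_1p5h",
    "bolus_1p5_to_3p5h",
    "bolus_none",
    "type_aerobic",
    "type_anaerobic",
    "type_mixed",
    "tod_morning",
    "tod_afternoon",
    "tod_evening",
    "sex_female",
    "modality_mdi",
    "modality_pump",
    "modality_closed_loop",
    "intensity_ordinal",
    "age_years",
    "years_since_diagnosis",
    "bmi",
    "hba1c_mmol_mol",
]

#: the three-variable simplified feature set
SIMPLIFIED_FEATURES = ["starting_glucose", "duration_min", "roc_falling"]

#: extended set: candidates plus IOB/kg and the pre-hour CGM metrics
EXTENDED_FEATURES = CANDIDATE_FEATURES + ["iob_per_kg"] + PRIOR_HOUR_FEATURES

#: default free-text exercise label -> predominant type mapping
DEFAULT_EXERCISE_TYPE_MAP = {
    "running": "aerobic",
    "cycling": "aerobic",
    "walking": "aerobic",
    "swimming": "aerobic",
    "rowing": "aerobic",
    "weightlifting": "anaerobic",
    "resistance training": "anaerobic",
    "sprinting": "anaerobic",
    "climbing": "anaerobic",
    "circuit training": "mixed",
    "football": "mixed",
    "tennis": "mixed",
    "hiit": "mixed",
}

_INTENSITY_ORDINAL = {"light": 0.0, "moderate": 1.0, "vigorous": 2.0}


def borg_to_intensity(borg) -> str | float:
    """Map a Borg RPE score (6–20) to light/moderate/vigorous.

    Scores <12 are light, 12–14 moderate, >14 vigorous.  Out-of-range or
    unparseable values return NaN and flow to imputation.
    """
    try:
        b = int(borg)
    except (TypeError, ValueError):
        return np.nan
    if not 6 <= b <= 20:
        return np.nan
    if b < 12:
        return "light"
    if b <= 14:
        return "moderate"
    return "vigorous"


def time_of_day(start: pd.Timestamp) -> str:
    """Morning [05:00, 12:00), afternoon [12:00, 17:00), evening otherwise."""
    h = start.hour + start.minute / 60.0
    if 5.0 <= h < 12.0:
        return "morning"
    if 12.0 <= h < 17.0:
        return "afternoon"
    return "evening"


def map_exercise_type(label: str, mapping: dict[str, str] | None = None) -> str | float:
    """Case-folded lookup of a free-text label; unmapped labels become NaN."""
    mapping = DEFAULT_EXERCISE_TYPE_MAP if mapping is None else mapping
    folded = {k.casefold().strip(): v for k, v in mapping.items()}
    return folded.get(str(label).casefold().strip(), np.nan)


def _intensity(bout: bouts_mod.ExerciseBout) -> str | float:
    if bout.intensity_scale == "borg":
        return borg_to_intensity(bout.intensity_raw)
    raw = str(bout.intensity_raw).casefold().strip()
    return raw if raw in _INTENSITY_ORDINAL else np.nan


def assemble(
    participants: pd.DataFrame,
    series: dict[str, cgm.GlucoseSeries],
    boluses: dict[str, list[insulin.BolusEvent]],
    included: list[tuple[bouts_mod.ExerciseBout, bouts_mod.BoutOutcome]],
    exercise_type_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One predictor row per included bout.

    ``participants`` must carry one row per participant_id with the
    metadata columns; an error lists any participants absent from it.
    Missing values (no fresh starting reading, unknown weight, unmapped
    labels) are left NaN for downstream imputation; the outcome label is
    always present.
    """
    meta = participants.set_index(participants["participant_id"].astype(str))
    needed = {b.participant_id for b, _ in included}
    missing_meta = sorted(needed - set(meta.index))
    if missing_meta:
        raise ValueError(f"no metadata for participants: {missing_meta}")

    rows = []
    for bout, outcome in included:
        s = series[bout.participant_id]
        m = meta.loc[bout.participant_id]
        start_g = cgm.starting_glucose(s, bout.start)
        roc = cgm.rate_of_change(s, bout.start)
        trend = cgm.classify_trend(roc).value if roc is not None else np.nan
        weight = m.get("weight_kg", np.nan)
        weight = float(weight) if pd.notna(weight) else None
        iob = insulin.iob_result(boluses.get(bout.participant_id, []), bout.start, weight)
        prior = cgm.window_metrics(s, bout.start - pd.Timedelta(minutes=60), bout.start)
        row = {
            "participant_id": bout.participant_id,
            "bout_id": bout.bout_id,
            "label": int(outcome.hypo),
            "starting_glucose": np.nan if start_g is None else start_g,
            "duration_min": bout.duration_min,
            "roc": np.nan if roc is None else roc,
            "trend": trend,
            "time_of_day": time_of_day(bout.start),
            "intensity": _intensity(bout),
            "exercise_type": map_exercise_type(bout.exercise_label, exercise_type_map),
            "bolus_category": iob.bolus_category,
            "iob_per_kg": np.nan if iob.iob_per_kg is None else iob.iob_per_kg,
            "age_years": float(m["age_years"]),
            "sex": m["sex"],
            "bmi": float(m["bmi"]),
            "hba1c_mmol_mol": float(m["hba1c_mmol_mol"]),
            "years_since_diagnosis": float(m["years_since_diagnosis"]),
            "insulin_modality": m["insulin_modality"],
        }
        for name, attr in zip(
            PRIOR_HOUR_FEATURES,
            ["mean", "sd", "cv", "tir_normal", "tir_tight", "tbr_l1", "tbr_l2", "tar_l1", "tar_l2"],
        ):
            row[name] = getattr(prior, attr) if prior is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def dummy_expand(table: pd.DataFrame) -> pd.DataFrame:
    """Add indicator columns for every categorical level plus the intensity
    ordinal; raw categorical columns are kept alongside."""
    out = table.copy()
    for col, level_map in DUMMY_COLUMNS.items():
        if col not in out.columns:
            continue
        for level, dummy in level_map.items():
            vals = out[col].astype(object)
            out[dummy] = np.where(
                vals.isna(), np.nan, (vals == level).astype(float)
            )
    if "intensity" in out.columns:
        out["intensity_ordinal"] = out["intensity"].map(_INTENSITY_ORDINAL)
    return out


# ---------------------------------------------------------------------------
# k-nn imputation


@dataclass
class KnnImputer:
    """Mixed-type k-nn imputer with an explicit fit/transform split so the
    reference statistics come from training folds only.

    Distances are Euclidean over the mutually observed continuous features,
    each standardised to the reference mean/variance, normalised by the
    number of features used.  Missing continuous cells take the mean of the
    k nearest donors with that feature observed; missing categorical cells
    take the donors' majority vote, ties resolved by the overall most
    frequent class.  Labels never participate.
    """

    k: int = 5
    continuous: tuple[str, ...] = tuple(CONTINUOUS_FEATURES + PRIOR_HOUR_FEATURES)
    categorical: tuple[str, ...] = tuple(CATEGORICAL_FEATURES)

    def fit(self, table: pd.DataFrame) -> "KnnImputer":
        self.cont_ = [c for c in self.continuous if c in table.columns]
        self.cat_ = [c for c in self.categorical if c in table.columns]
        for c in self.cont_ + self.cat_:
            if table[c].isna().all():
                raise ValueError(f"feature {c!r} is missing in every reference row")
        ref = table[self.cont_].to_numpy(dtype=float)
        self.mu_ = np.nanmean(ref, axis=0)
        sd = np.nanstd(ref, axis=0)
        sd[~np.isfinite(sd) | (sd == 0)] = 1.0
        self.sd_ = sd
        self.ref_z_ = (ref - self.mu_) / self.sd_
        self.ref_cont_raw_ = ref
        self.ref_cat_ = {c: table[c].to_numpy(dtype=object) for c in self.cat_}
        self.cat_mode_ = {
            c: table[c].dropna().value_counts().index[0] for c in self.cat_
        }
        return self

    def _distances(self, z_row: np.ndarray) -> np.ndarray:
        obs = np.isfinite(z_row)
        mutual = obs[None, :] & np.isfinite(self.ref_z_)
        n_used = mutual.sum(axis=1)
        diff = np.where(mutual, self.ref_z_ - z_row[None, :], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt((diff**2).sum(axis=1) / n_used)
        d[n_used == 0] = np.inf
        return d

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        z = (out[self.cont_].to_numpy(dtype=float) - self.mu_) / self.sd_
        cont_idx = {c: j for j, c in enumerate(self.cont_)}
        need = out[self.cont_].isna().any(axis=1) | out[self.cat_].isna().any(axis=1)
        for i in np.flatnonzero(need.to_numpy()):
            d = self._distances(z[i])
            order = np.argsort(d, kind="stable")
            for c in self.cont_:
                j = cont_idx[c]
                if np.isfinite(z[i, j]) or not np.isnan(
                    out.iloc[i, out.columns.get_loc(c)]
                ):
                    continue
                donors = order[np.isfinite(self.ref_cont_raw_[order, j]) & np.isfinite(d[order])]
                donors = donors[: self.k]
                if len(donors) == 0:
                    out.iloc[i, out.columns.get_loc(c)] = self.mu_[j]
                else:
                    out.iloc[i, out.columns.get_loc(c)] = float(
                        np.mean(self.ref_cont_raw_[donors, j])
                    )
            for c in self.cat_:
                if not pd.isna(out.iloc[i, out.columns.get_loc(c)]):
                    continue
                ref_vals = self.ref_cat_[c]
                mask = np.array([not pd.isna(v) for v in ref_vals])
                donors = order[mask[order] & np.isfinite(d[order])][: self.k]
                if len(donors) == 0:
                    out.iloc[i, out.columns.get_loc(c)] = self.cat_mode_[c]
                    continue
                votes = pd.Series(ref_vals[donors]).value_counts()
                top = votes[votes == votes.max()]
                if len(top) == 1:
                    out.iloc[i, out.columns.get_loc(c)] = top.index[0]
                else:
                    out.iloc[i, out.columns.get_loc(c)] = self.cat_mode_[c]
        return out


def impute_knn(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute a table against itself (fit and transform on the same rows)."""
    return KnnImputer(k=k).fit(table).transform(table)


def read_participants_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"participant_id": str})
    return frame
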