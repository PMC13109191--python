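"""End-to-end orchestration: QC -> outcome labelling -> feature assembly ->
grouped CV training, as composable functions used by both the CLI and the
test-suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bouts as bouts_mod
from . import features as features_mod
from . import model as model_mod
from .cgm import GlucoseSeries
from .insulin import BolusEvent


def preprocess(
    participants: pd.DataFrame,
    series: dict[str, GlucoseSeries],
    boluses: dict[str, list[BolusEvent]],
    bouts: dict[str, list[bouts_mod.ExerciseBout]],
    exercise_type_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run QC and outcome labelling, then assemble the per-bout feature table.

    Returns ``(feature_table, qc_report)``; the report carries one row per
    logged bout with its inclusion verdict and reasons.
    """
    included: list[tuple[bouts_mod.ExerciseBout, bouts_mod.BoutOutcome]] = []
    qc_frames = []
    for pid in sorted(bouts):
        p_bouts = bouts[pid]
        p_series = series.get(pid)
        qcs = bouts_mod.qc_participant(p_bouts, p_series)
        rep = bouts_mod.qc_report(qcs)
        rep.insert(0, "participant_id", pid)
        qc_frames.append(rep)
        for b in p_bouts:
            if qcs[b.bout_id].included:
                included.append((b, bouts_mod.label_outcome(b, p_series)))
    qc = pd.concat(qc_frames, ignore_index=True) if qc_frames else pd.DataFrame()
    table = features_mod.assemble(
        participants, series, boluses, included, exercise_type_map
    )
    return table, qc


def exclusion_counts(qc: pd.DataFrame) -> dict[str, int]:
    """Number of excluded bouts carrying each exclusion reason."""
    counts = {r: 0 for r in bouts_mod.EXCLUSION_REASONS}
    for reasons in qc.loc[~qc["included"], "reasons"]:
        for r in str(reasons).split(";"):
            if r:
                counts[r] += 1
    return counts


def train_simplified(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    params: dict | None = None,
    tune_budget: int = 0,
    monotone: bool = False,
) -> model_mod.TrainedEnsemble:
    """Grouped stratified CV training of the three-variable simplified model."""
    return _train(table, model_mod_features_simplified(), k, seed, params, tune_budget, monotone)


def train_extended(
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    params: dict | None = None,
    tune_budget: int = 0,
) -> model_mod.TrainedEnsemble:
    """CV training on the extended feature set (candidates + pre-hour CGM metrics)."""
    return _train(table, list(features_mod.EXTENDED_FEATURES), k, seed, params, tune_budget, False)


def model_mod_features_simplified() -> list[str]:
    return list(features_mod.SIMPLIFIED_FEATURES)


def _train(table, feats, k, seed, params, tune_budget, monotone):
    plan = model_mod.make_folds(table, k=k, seed=seed)
    fold_data = model_mod.prepare_fold_data(table, plan)
    if tune_budget > 0:
        params = model_mod.tune(
            table, plan, feats, budget=tune_budget, seed=seed, fold_data=fold_data
        )
    return model_mod.train_cv(
        table, plan, feats, params, seed=seed, monotone=monotone, fold_data=fold_data
    )


def metrics_dict(ensemble: model_mod.TrainedEnsemble) -> dict:
    """JSON-serialisable summary of a trained ensemble."""
    return {
        "features": ensemble.features,
        "k": ensemble.fold_plan.k,
        "seed": ensemble.seed,
        "params": {k: (v.item() if hasattr(v, "item") else v) for k, v in ensemble.params.items()},
        "auc_mean": round(float(ensemble.auc_mean), 10),
        "auc_ci": [round(float(x), 10) for x in ensemble.auc_ci],
        "sensitivity": round(float(ensemble.sensitivity), 10),
        "specificity": round(float(ensemble.specificity), 10),
        "threshold": round(float(ensemble.threshold), 10),
        "fold_auc": [round(float(x), 10) for x in ensemble.fold_metrics["auc"]],
    }


def write_features_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.8g")


def read_features_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"participant_id": str, "bout_id": str})
    table["label"] = table["label"].astype(int)
    return table
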