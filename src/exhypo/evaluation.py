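"""Calibration curves, subgroup observed-vs-predicted analysis and the
external-validation harness.

The mean signed deviation (MSD) of a subgroup level is its observed
hypoglycaemia rate minus its mean predicted rate, in percentage points;
positive MSD means the model under-predicts risk for that level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import ModelError, TrainedEnsemble, auc_mean_ci, predict_ensemble, roc_auc, sens_spec

#: subgroup variables reported by default; continuous ones are tercile-binned
DEFAULT_SUBGROUP_CONTINUOUS = [
    "starting_glucose",
    "duration_min",
    "roc",
    "iob_per_kg",
    "age_years",
    "years_since_diagnosis",
    "hba1c_mmol_mol",
    "prior_cv",
]
DEFAULT_SUBGROUP_CATEGORICAL = [
    "sex",
    "insulin_modality",
    "exercise_type",
    "intensity",
    "time_of_day",
]


def calibration_curve(
    predictions, labels, n_bins: int = 10, scheme: str = "quantile"
) -> pd.DataFrame:
    """Reliability table: per-bin mean predicted probability vs observed rate.

    ``quantile`` bins hold roughly equal counts; ``uniform`` bins split
    [0, 1] evenly.  Bin counts always sum to the number of rows.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predictions must lie in [0, 1]")
    if scheme == "quantile":
        edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
        if len(edges) < 2:
            edges = np.array([0.0, 1.0])
    elif scheme == "uniform":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    edges = edges.copy()
    edges[0], edges[-1] = -np.inf, np.inf  # half-open interior, catch-all ends
    idx = np.searchsorted(edges, p, side="right") - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue
        rows.append(
            {
                "bin": b,
                "lower": float(p[mask].min()),
                "upper": float(p[mask].max()),
                "mean_predicted": float(p[mask].mean()),
                "observed_rate": float(y[mask].mean()),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def subgroup_analysis(
    predictions, labels, subgroup_assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per-level n, observed %, predicted %, MSD (pp) and ROC AUC.

    ``subgroup_assignments`` holds one column per subgroup variable; each
    column's values are that row's level.  An ``all subgroups`` row reports
    the overall quantities.  Levels where AUC is undefined (single class)
    get NaN AUC; empty levels are skipped with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    rows = [_subgroup_row("all subgroups", "all", p, y)]
    for var in subgroup_assignments.columns:
        col = subgroup_assignments[var]
        for level in pd.unique(col.dropna()):
            mask = (col == level).to_numpy()
            if not mask.any():
                warnings.warn(f"empty level {level!r} of {var!r} skipped")
                continue
            rows.append(_subgroup_row(var, str(level), p[mask], y[mask]))
    return pd.DataFrame(rows)


def _subgroup_row(variable: str, level: str, p: np.ndarray, y: np.ndarray) -> dict:
    observed = 100.0 * float(y.mean())
    predicted = 100.0 * float(p.mean())
    try:
        auc = roc_auc(p, y)
    except ModelError:
        auc = np.nan
    return {
        "variable": variable,
        "level": level,
        "n": len(y),
        "observed_pct": observed,
        "predicted_pct": predicted,
        "msd_pp": observed - predicted,
        "roc_auc": auc,
    }


def tercile_bins(values: pd.Series, name: str) -> pd.Series:
    """Label values low/mid/high by terciles (NaN stays NaN)."""
    try:
        binned = pd.qcut(values, 3, labels=[f"{name} low", f"{name} mid", f"{name} high"],
                         duplicates="drop")
    except ValueError:
        return pd.Series(np.nan, index=values.index)
    return binned.astype(object)


def default_subgroups(table: pd.DataFrame) -> pd.DataFrame:
    """Assemble the default subgroup assignment frame from a feature table."""
    out = {}
    for var in DEFAULT_SUBGROUP_CONTINUOUS:
        if var in table.columns:
            out[var] = tercile_bins(table[var], var)
    for var in DEFAULT_SUBGROUP_CATEGORICAL:
        if var in table.columns:
            out[var] = table[var].astype(object)
    return pd.DataFrame(out, index=table.index)


def external_validate(
    ensemble: TrainedEnsemble, table: pd.DataFrame, n_bins: int = 10
) -> dict:
    """Score an externally prepared cohort with the fold ensemble.

    The cohort must have been pushed through the identical preprocessing
    (QC -> feature assembly).  Returns ensemble-mean ROC AUC with a CI
    across fold models, sensitivity/specificity at the carried-over
    threshold, a calibration table and a subgroup report.
    """
    if "label" not in table.columns or table["label"].isna().any():
        raise ModelError("external cohort must carry outcome labels")
    table = table.reset_index(drop=True)
    preds = predict_ensemble(ensemble, table)
    y = table["label"].to_numpy()
    per_fold_auc = []
    for clf, imputer in zip(ensemble.fold_models, ensemble.fold_imputers):
        from .features import dummy_expand

        t = table
        if imputer is not None and all(
            c in table.columns for c in list(imputer.cont_) + list(imputer.cat_)
        ):
            t = imputer.transform(table)
        p = clf.predict_proba(dummy_expand(t)[ensemble.features])[:, 1]
        per_fold_auc.append(roc_auc(p, y))
    auc_mean, auc_ci = auc_mean_ci(per_fold_auc)
    sens, spec = sens_spec(preds["mean"], y, ensemble.threshold)
    return {
        "n": len(table),
        "observed_rate_pct": 100.0 * float(np.mean(y)),
        "auc_mean": auc_mean,
        "auc_ci": auc_ci,
        "sensitivity": sens,
        "specificity": spec,
        "threshold": ensemble.threshold,
        "calibration": calibration_curve(preds["mean"], y, n_bins=n_bins),
        "subgroups": subgroup_analysis(preds["mean"], y, default_subgroups(table)),
        "predictions": preds,
    }
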