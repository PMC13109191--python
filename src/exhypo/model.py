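"""Participant-grouped stratified cross-validation and gradient-boosted
modelling of exercise hypoglycaemia.

Folds group whole participants (repeated-measures structure: a
participant's bouts never straddle folds) while a greedy heuristic keeps
per-fold bout-level hypoglycaemia prevalence close to the global rate.
Training produces a k-model ensemble with out-of-fold probabilities, a
Youden-J decision threshold, and per-fold ROC AUC / sensitivity /
specificity with normal-approximation 95% CIs across folds.  Hyperparameter
search is a seeded random search over a fixed grid; forward feature
selection greedily grows the feature set by mean CV ROC AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from xgboost import XGBClassifier

from .features import KnnImputer, dummy_expand

#: default boosted-tree settings; tune() searches around these
DEFAULT_PARAMS: dict = {
    "n_estimators": 200,
    "max_depth": 3,
    "learning_rate": 0.08,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
    "min_child_weight": 5,
    "reg_lambda": 1.0,
}

_SEARCH_GRID: dict[str, list] = {
    "n_estimators": [100, 200, 300],
    "max_depth": [2, 3, 4, 5],
    "learning_rate": [0.03, 0.05, 0.08, 0.15],
    "subsample": [0.7, 0.85, 1.0],
    "colsample_bytree": [0.6, 0.8, 1.0],
    "min_child_weight": [1, 5, 10],
    "reg_lambda": [0.5, 1.0, 5.0],
}

#: monotone directions for the simplified heatmap model (optional training mode)
MONOTONE_DIRECTIONS = {"starting_glucose": -1, "duration_min": 1, "roc_falling": 1}


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class FoldPlan:
    """Participant -> fold assignment for grouped stratified CV."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_of(self, participant_ids: pd.Series) -> np.ndarray:
        return participant_ids.map(self.assignment).to_numpy()


@dataclass
class TrainedEnsemble:
    """k per-fold boosted-tree models plus out-of-fold scores and metrics."""

    fold_models: list
    fold_imputers: list
    features: list[str]
    params: dict
    fold_plan: FoldPlan
    oof: np.ndarray
    threshold: float
    fold_metrics: pd.DataFrame
    auc_mean: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    seed: int
    monotone: bool = False


def make_folds(table: pd.DataFrame, k: int = 10, seed: int = 0) -> FoldPlan:
    """Greedy balanced grouped-fold assignment.

    Participants are processed in decreasing order of (hypo-bout count,
    total bouts); each goes to the fold that minimises a combined deviation
    of fold prevalence from the global rate and fold size from parity.
    Deterministic for a given seed (the seed only breaks sorting ties).
    """
    counts = table.groupby("participant_id")["label"].agg(["sum", "count"])
    if len(counts) < k:
        raise ModelError(f"need at least k={k} participants, got {len(counts)}")
    if table["label"].nunique() < 2:
        raise ModelError("both outcome classes must be present")
    rng = np.random.default_rng(seed)
    tie = pd.Series(rng.random(len(counts)), index=counts.index)
    order = counts.assign(tie=tie).sort_values(
        ["sum", "count", "tie"], ascending=[False, False, True]
    )
    total_pos = counts["sum"].sum()
    total_n = counts["count"].sum()
    global_rate = total_pos / total_n
    target_size = total_n / k
    fold_pos = np.zeros(k)
    fold_tot = np.zeros(k)
    assignment: dict[str, int] = {}
    for pid, row in order.iterrows():
        # marginal change in the fold's absolute positive-count imbalance,
        # plus a size term: dilution of an over-prevalent fold is rewarded
        imb_before = np.abs(fold_pos - global_rate * fold_tot)
        imb_after = np.abs(
            fold_pos + row["sum"] - global_rate * (fold_tot + row["count"])
        )
        size_term = (fold_tot + row["count"]) / target_size
        cost = (imb_after - imb_before) / max(row["count"], 1) + 0.1 * size_term
        f = int(np.argmin(cost))
        assignment[str(pid)] = f
        fold_pos[f] += row["sum"]
        fold_tot[f] += row["count"]
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ModelError("ROC AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_mean_ci(fold_aucs) -> tuple[float, tuple[float, float]]:
    """Mean and normal-approximation 95% CI over per-fold AUCs."""
    a = np.asarray(fold_aucs, dtype=float)
    mean = float(a.mean())
    half = 1.96 * float(a.std(ddof=1)) / np.sqrt(len(a)) if len(a) > 1 else 0.0
    return mean, (mean - half, mean + half)


def youden_threshold(scores, labels) -> float:
    """Probability threshold maximising Youden's J = sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    t = float(thr[int(np.argmax(j))])
    return float(min(max(t, 1e-6), 1.0 - 1e-6))


def sens_spec(scores, labels, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity of the rule ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    tp = np.count_nonzero(pred & labels)
    fn = np.count_nonzero(~pred & labels)
    tn = np.count_nonzero(~pred & ~labels)
    fp = np.count_nonzero(pred & ~labels)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def _make_classifier(params: dict, seed: int, features: list[str], monotone: bool,
                     scale_pos_weight: float = 1.0) -> XGBClassifier:
    kwargs = dict(
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        scale_pos_weight=scale_pos_weight,
        **params,
    )
    if monotone:
        kwargs["monotone_constraints"] = tuple(
            MONOTONE_DIRECTIONS.get(f, 0) for f in features
        )
    return XGBClassifier(**kwargs)


def prepare_fold_data(
    table: pd.DataFrame,
    fold_plan: FoldPlan,
    impute: bool = True,
    knn_k: int = 5,
) -> list[dict]:
    """Per-fold imputed and dummy-expanded train/validation matrices.

    Imputation is fitted on the training folds only and applied to the
    validation fold, so no validation information leaks into the fill-in
    values.  The result is reusable across feature subsets (tuning and
    forward selection slice columns from it).
    """
    table = table.reset_index(drop=True)
    folds = fold_plan.fold_of(table["participant_id"])
    if np.any(pd.isna(folds)):
        missing = sorted(set(table["participant_id"][pd.isna(folds)]))
        raise ModelError(f"participants missing from fold plan: {missing}")
    out = []
    for f in range(fold_plan.k):
        val_mask = folds == f
        train = table[~val_mask]
        val = table[val_mask]
        if train["label"].nunique() < 2:
            raise ModelError(f"training folds for fold {f} contain a single class")
        imputer = None
        if impute:
            imputer = KnnImputer(k=knn_k).fit(train)
            train = imputer.transform(train)
            val = imputer.transform(val)
        out.append(
            {
                "fold": f,
                "train": dummy_expand(train),
                "val": dummy_expand(val),
                "val_index": np.flatnonzero(val_mask),
                "imputer": imputer,
            }
        )
    return out


def train_cv(
    table: pd.DataFrame,
    fold_plan: FoldPlan,
    features: list[str],
    params: dict | None = None,
    seed: int = 0,
    impute: bool = True,
    monotone: bool = False,
    fold_data: list[dict] | None = None,
) -> TrainedEnsemble:
    """Fit one boosted-tree classifier per fold and collect out-of-fold scores."""
    params = dict(DEFAULT_PARAMS if params is None else params)
    table = table.reset_index(drop=True)
    if fold_data is None:
        fold_data = prepare_fold_data(table, fold_plan, impute=impute)
    oof = np.full(len(table), np.nan)
    models, imputers, rows = [], [], []
    for fd in fold_data:
        X_tr = fd["train"][features]
        y_tr = fd["train"]["label"].to_numpy()
        clf = _make_classifier(params, seed + fd["fold"], features, monotone)
        clf.fit(X_tr, y_tr)
        p_val = clf.predict_proba(fd["val"][features])[:, 1]
        oof[fd["val_index"]] = p_val
        models.append(clf)
        imputers.append(fd["imputer"])
        y_val = fd["val"]["label"].to_numpy()
        fold_auc = roc_auc(p_val, y_val) if len(np.unique(y_val)) > 1 else np.nan
        fold_thr = (
            youden_threshold(p_val, y_val) if len(np.unique(y_val)) > 1 else np.nan
        )
        rows.append({"fold": fd["fold"], "auc": fold_auc, "threshold": fold_thr})
    if np.isnan(oof).any():
        raise ModelError("some rows received no out-of-fold prediction")
    fold_metrics = pd.DataFrame(rows)
    valid_auc = fold_metrics["auc"].dropna()
    auc_mean, auc_ci = auc_mean_ci(valid_auc.to_numpy())
    threshold = float(fold_metrics["threshold"].dropna().mean())
    labels = table["label"].to_numpy()
    sens_list, spec_list = [], []
    for fd in fold_data:
        idx = fd["val_index"]
        s, sp = sens_spec(oof[idx], labels[idx], threshold)
        sens_list.append(s)
        spec_list.append(sp)
    fold_metrics["sensitivity"] = sens_list
    fold_metrics["specificity"] = spec_list
    return TrainedEnsemble(
        fold_models=models,
        fold_imputers=imputers,
        features=list(features),
        params=params,
        fold_plan=fold_plan,
        oof=oof,
        threshold=threshold,
        fold_metrics=fold_metrics,
        auc_mean=auc_mean,
        auc_ci=auc_ci,
        sensitivity=float(np.nanmean(sens_list)),
        specificity=float(np.nanmean(spec_list)),
        seed=seed,
        monotone=monotone,
    )


def tune(
    table: pd.DataFrame,
    fold_plan: FoldPlan,
    features: list[str],
    budget: int = 25,
    seed: int = 0,
    fold_data: list[dict] | None = None,
) -> dict:
    """Seeded budgeted random search over the documented grid.

    Candidate 0 is always the default configuration, so the selected
    configuration can never score below it on the searched set.  Ties keep
    the earliest candidate.
    """
    if budget < 1:
        raise ModelError("tuning budget must be >= 1")
    rng = np.random.default_rng(seed)
    candidates = [dict(DEFAULT_PARAMS)]
    while len(candidates) < budget:
        cand = {k: v[rng.integers(len(v))] for k, v in _SEARCH_GRID.items()}
        candidates.append(cand)
    if fold_data is None:
        fold_data = prepare_fold_data(table, fold_plan)
    best, best_auc = None, -np.inf
    for cand in candidates:
        ens = train_cv(table, fold_plan, features, cand, seed=seed, fold_data=fold_data)
        if ens.auc_mean > best_auc:
            best, best_auc = cand, ens.auc_mean
    return dict(best)


@dataclass
class SelectionTrajectory:
    """Greedy forward-selection path: (feature added, mean CV AUC, delta)."""

    steps: pd.DataFrame  # columns: step, feature, auc, delta

    @property
    def order(self) -> list[str]:
        return self.steps["feature"].tolist()


def forward_select(
    table: pd.DataFrame,
    fold_plan: FoldPlan,
    candidates: list[str],
    params: dict | None = None,
    seed: int = 0,
    max_steps: int | None = None,
    fold_data: list[dict] | None = None,
) -> SelectionTrajectory:
    """Greedy forward selection by mean CV ROC AUC.

    At each step the candidate giving the highest mean CV AUC when added to
    the current set is appended (ties: candidate list order).  The full
    trajectory is reported — including steps with zero or negative deltas —
    unless ``max_steps`` truncates it.
    """
    if not candidates:
        raise ModelError("at least one candidate feature is required")
    if fold_data is None:
        fold_data = prepare_fold_data(table, fold_plan)
    remaining = list(candidates)
    selected: list[str] = []
    rows = []
    prev_auc = 0.5  # chance level: the no-feature baseline
    n_steps = len(candidates) if max_steps is None else min(max_steps, len(candidates))
    for step in range(n_steps):
        best_feat, best_auc = None, -np.inf
        for feat in remaining:
            ens = train_cv(
                table, fold_plan, selected + [feat], params, seed=seed, fold_data=fold_data
            )
            if ens.auc_mean > best_auc:
                best_feat, best_auc = feat, ens.auc_mean
        selected.append(best_feat)
        remaining.remove(best_feat)
        rows.append(
            {
                "step": step + 1,
                "feature": best_feat,
                "auc": best_auc,
                "delta": best_auc - prev_auc,
            }
        )
        prev_auc = best_auc
    return SelectionTrajectory(pd.DataFrame(rows))


def predict_ensemble(ensemble: TrainedEnsemble, table: pd.DataFrame) -> pd.DataFrame:
    """Score rows with every fold model: per-row mean and 95% CI across folds.

    Each fold model applies its own training-fold imputer first (when the
    ensemble was trained with imputation), mirroring how that model saw data
    during CV.
    """
    missing = [f for f in ensemble.features if f not in dummy_expand_columns(table)]
    if missing:
        raise ModelError(f"table lacks required feature columns: {missing}")
    preds = []
    for clf, imputer in zip(ensemble.fold_models, ensemble.fold_imputers):
        t = table
        if imputer is not None and all(
            c in table.columns for c in list(imputer.cont_) + list(imputer.cat_)
        ):
            t = imputer.transform(table)
        preds.append(clf.predict_proba(dummy_expand(t)[ensemble.features])[:, 1])
    p = np.vstack(preds)
    mean = p.mean(axis=0)
    half = 1.96 * p.std(axis=0, ddof=1) / np.sqrt(p.shape[0])
    return pd.DataFrame(
        {"mean": mean, "ci_lo": mean - half, "ci_hi": mean + half},
        index=table.index,
    )


def dummy_expand_columns(table: pd.DataFrame) -> set[str]:
    """Columns available after dummy expansion, without materialising it."""
    from .features import DUMMY_COLUMNS

    cols = set(table.columns) | {"intensity_ordinal"}
    for col, level_map in DUMMY_COLUMNS.items():
        if col in table.columns:
            cols.update(level_map.values())
    return cols


def assert_no_leakage(ensemble: TrainedEnsemble, table: pd.DataFrame) -> None:
    """Raise unless every out-of-fold score came from a model whose training
    folds excluded the row's participant."""
    table = table.reset_index(drop=True)
    folds = ensemble.fold_plan.fold_of(table["participant_id"])
    for f in range(ensemble.fold_plan.k):
        val_pids = set(table["participant_id"][folds == f])
        train_pids = set(table["participant_id"][folds != f])
        if val_pids & train_pids:
            raise ModelError(
                f"participants {sorted(val_pids & train_pids)} appear on both "
                f"sides of fold {f}"
            )


# ---------------------------------------------------------------------------
# serialisation


def save_ensemble(ensemble: TrainedEnsemble, directory) -> Path:
    """Serialise fold models (XGBoost JSON) plus metadata to a directory.

    Imputers are not serialised: a loaded bundle scores tables as-is, with
    any remaining NaN handled by XGBoost's native missing-value routing.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, clf in enumerate(ensemble.fold_models):
        clf.get_booster().save_model(str(directory / f"fold_{i:02d}.json"))
    meta = {
        "features": ensemble.features,
        "params": {k: (v.item() if hasattr(v, "item") else v) for k, v in ensemble.params.items()},
        "threshold": ensemble.threshold,
        "seed": ensemble.seed,
        "monotone": ensemble.monotone,
        "k": ensemble.fold_plan.k,
        "fold_assignment": ensemble.fold_plan.assignment,
        "fold_seed": ensemble.fold_plan.seed,
        "auc_mean": ensemble.auc_mean,
        "auc_ci": list(ensemble.auc_ci),
        "sensitivity": ensemble.sensitivity,
        "specificity": ensemble.specificity,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    ensemble.fold_metrics.to_csv(directory / "fold_metrics.csv", index=False)
    return directory


def load_ensemble(directory) -> TrainedEnsemble:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    models = []
    for i in range(meta["k"]):
        clf = XGBClassifier()
        clf.load_model(str(directory / f"fold_{i:02d}.json"))
        models.append(clf)
    fold_metrics = pd.read_csv(directory / "fold_metrics.csv")
    return TrainedEnsemble(
        fold_models=models,
        fold_imputers=[None] * meta["k"],
        features=meta["features"],
        params=meta["params"],
        fold_plan=FoldPlan(meta["k"], meta["fold_assignment"], meta["fold_seed"]),
        oof=np.array([]),
        threshold=meta["threshold"],
        fold_metrics=fold_metrics,
        auc_mean=meta["auc_mean"],
        auc_ci=tuple(meta["auc_ci"]),
        sensitivity=meta["sensitivity"],
        specificity=meta["specificity"],
        seed=meta["seed"],
        monotone=meta["monotone"],
    )
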