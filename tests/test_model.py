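"""Grouped stratified folds, CV training, metrics and selection logic."""

import numpy as np
import pandas as pd
import pytest

from exhypo import model
from exhypo.features import SIMPLIFIED_FEATURES


class TestMakeFolds:
    def test_every_participant_in_exactly_one_fold(self, big_table):
        table, _ = big_table
        plan = model.make_folds(table, k=10, seed=0)
        pids = set(table["participant_id"])
        assert set(plan.assignment) == pids
        assert set(plan.assignment.values()) <= set(range(10))

    def test_no_participant_split_across_folds(self, big_table):
        table, _ = big_table
        plan = model.make_folds(table, k=10, seed=0)
        folds = plan.fold_of(table["participant_id"])
        per_pid = pd.DataFrame({"pid": table["participant_id"], "fold": folds})
        assert (per_pid.groupby("pid")["fold"].nunique() == 1).all()

    def test_prevalence_within_three_points_of_global(self, big_table):
        table, _ = big_table
        for k in (4, 10):
            plan = model.make_folds(table, k=k, seed=0)
            folds = plan.fold_of(table["participant_id"])
            global_rate = table["label"].mean()
            prev = table.groupby(folds)["label"].mean()
            assert (prev - global_rate).abs().max() < 0.03

    def test_too_few_participants_is_error(self, small_table):
        table, _ = small_table
        with pytest.raises(model.ModelError):
            model.make_folds(table, k=100)

    def test_deterministic_given_seed(self, small_table):
        table, _ = small_table
        a = model.make_folds(table, k=5, seed=7)
        b = model.make_folds(table, k=5, seed=7)
        assert a.assignment == b.assignment


class TestRocAuc:
    def test_perfect_separation(self):
        assert model.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_small_fixture_pair_count(self):
        # 4 positive-negative pairs: 3 wins, 1 loss -> 0.75
        assert model.roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert model.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_is_error(self):
        with pytest.raises(model.ModelError):
            model.roc_auc([0.1, 0.9], [1, 1])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        a = model.roc_auc(scores, labels)
        assert model.roc_auc(np.exp(3 * scores), labels) == pytest.approx(a)

    def test_matches_brute_force_pair_counting(self):
        """Rank-based AUC equals explicit counting of wins and half-ties over
        all positive-negative pairs, on 200 random score/label sets."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (len(pos) * len(neg))
            assert model.roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestThresholdAndSensSpec:
    def test_perfectly_separated(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        t = model.youden_threshold(scores, labels)
        sens, spec = model.sens_spec(scores, labels, t)
        assert sens == 1.0 and spec == 1.0

    def test_zero_threshold_degenerate(self):
        sens, spec = model.sens_spec([0.2, 0.8, 0.5], [1, 0, 1], 0.0)
        assert sens == 1.0 and spec == 0.0

    def test_hand_computed_confusion_matrix(self):
        scores = [0.9, 0.7, 0.6, 0.4, 0.35, 0.3, 0.2, 0.05]
        labels = [1, 1, 0, 1, 0, 0, 0, 0]
        sens, spec = model.sens_spec(scores, labels, 0.5)
        assert sens == pytest.approx(2 / 3)  # 0.9, 0.7 above; 0.4 below
        assert spec == pytest.approx(4 / 5)  # only 0.6 above among negatives


class TestTrainCv:
    def test_oof_coverage_and_leakage_guard(self, big_table, simplified_ensemble):
        table, _ = big_table
        assert len(simplified_ensemble.oof) == len(table)
        assert not np.isnan(simplified_ensemble.oof).any()
        model.assert_no_leakage(simplified_ensemble, table)

    def test_strong_signal_recovered(self, simplified_ensemble):
        assert simplified_ensemble.auc_mean > 0.75

    def test_deterministic_retrain(self, small_table):
        table, _ = small_table
        plan = model.make_folds(table, k=5, seed=1)
        fd = model.prepare_fold_data(table, plan)
        a = model.train_cv(table, plan, SIMPLIFIED_FEATURES, seed=3, fold_data=fd)
        b = model.train_cv(table, plan, SIMPLIFIED_FEATURES, seed=3, fold_data=fd)
        assert np.array_equal(a.oof, b.oof)
        assert a.auc_mean == b.auc_mean and a.threshold == b.threshold


class TestTune:
    def test_budget_one_returns_default(self, small_table):
        table, _ = small_table
        plan = model.make_folds(table, k=5, seed=1)
        fd = model.prepare_fold_data(table, plan)
        params = model.tune(table, plan, SIMPLIFIED_FEATURES, budget=1, seed=0, fold_data=fd)
        assert params == model.DEFAULT_PARAMS

    def test_deterministic_and_at_least_default(self, small_table):
        table, _ = small_table
        plan = model.make_folds(table, k=5, seed=1)
        fd = model.prepare_fold_data(table, plan)
        a = model.tune(table, plan, SIMPLIFIED_FEATURES, budget=4, seed=2, fold_data=fd)
        b = model.tune(table, plan, SIMPLIFIED_FEATURES, budget=4, seed=2, fold_data=fd)
        assert a == b
        auc_sel = model.train_cv(table, plan, SIMPLIFIED_FEATURES, a, fold_data=fd).auc_mean
        auc_def = model.train_cv(table, plan, SIMPLIFIED_FEATURES, fold_data=fd).auc_mean
        assert auc_sel >= auc_def - 1e-12


class TestForwardSelect:
    def test_single_candidate_trajectory(self, small_table):
        table, _ = small_table
        plan = model.make_folds(table, k=5, seed=1)
        fd = model.prepare_fold_data(table, plan)
        traj = model.forward_select(table, plan, ["starting_glucose"], fold_data=fd)
        assert traj.order == ["starting_glucose"]
        assert len(traj.steps) == 1

    def test_first_pick_is_single_feature_argmax(self, small_table):
        """Consistency: step 1 equals the argmax of single-feature CV AUC."""
        table, _ = small_table
        plan = model.make_folds(table, k=5, seed=1)
        fd = model.prepare_fold_data(table, plan)
        cands = ["starting_glucose", "duration_min", "roc_falling", "age_years"]
        fast = dict(model.DEFAULT_PARAMS, n_estimators=60)
        traj = model.forward_select(table, plan, cands, params=fast, fold_data=fd, max_steps=1)
        singles = {
            c: model.train_cv(table, plan, [c], fast, fold_data=fd).auc_mean for c in cands
        }
        assert traj.order[0] == max(singles, key=singles.get)

    def test_pure_noise_candidate_adds_nothing(self, small_table):
        table, _ = small_table
        table = table.copy()
        rng = np.random.default_rng(0)
        table["pure_noise"] = rng.normal(size=len(table))
        plan = model.make_folds(table, k=5, seed=1)
        fd = model.prepare_fold_data(table, plan)
        fast = dict(model.DEFAULT_PARAMS, n_estimators=60)
        traj = model.forward_select(
            table, plan, ["starting_glucose", "duration_min", "pure_noise"],
            params=fast, fold_data=fd,
        )
        steps = traj.steps.set_index("feature")
        assert traj.order[0] != "pure_noise"
        assert abs(steps.loc["pure_noise", "delta"]) < 0.02


class TestPredictEnsemble:
    def test_mean_and_ci_shape(self, simplified_ensemble, big_table):
        table, _ = big_table
        preds = model.predict_ensemble(simplified_ensemble, table.head(50))
        assert list(preds.columns) == ["mean", "ci_lo", "ci_hi"]
        assert ((preds["ci_lo"] <= preds["mean"]) & (preds["mean"] <= preds["ci_hi"])).all()

    def test_missing_feature_column_is_error(self, simplified_ensemble):
        rows = pd.DataFrame({"starting_glucose": [7.0], "duration_min": [30.0]})
        with pytest.raises(model.ModelError, match="lacks"):
            model.predict_ensemble(simplified_ensemble, rows)

    def test_identical_models_have_zero_ci_width(self, simplified_ensemble):
        import copy

        ens = copy.copy(simplified_ensemble)
        ens.fold_models = [simplified_ensemble.fold_models[0]] * 5
        ens.fold_imputers = [None] * 5
        rows = pd.DataFrame(
            {"starting_glucose": [7.0, 4.5], "duration_min": [30.0, 60.0],
             "roc_falling": [0.0, 1.0]}
        )
        preds = model.predict_ensemble(ens, rows)
        assert np.allclose(preds["ci_hi"] - preds["ci_lo"], 0.0)


class TestSerialisation:
    def test_save_load_roundtrip_scores(self, simplified_ensemble, tmp_path):
        model.save_ensemble(simplified_ensemble, tmp_path / "bundle")
        loaded = model.load_ensemble(tmp_path / "bundle")
        assert loaded.features == simplified_ensemble.features
        assert loaded.threshold == pytest.approx(simplified_ensemble.threshold)
        rows = pd.DataFrame(
            {"starting_glucose": [7.0, 4.5], "duration_min": [30.0, 60.0],
             "roc_falling": [0.0, 1.0]}
        )
        a = model.predict_ensemble(simplified_ensemble, rows)["mean"]
        b = model.predict_ensemble(loaded, rows)["mean"]
        assert np.allclose(a, b, atol=1e-6)
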