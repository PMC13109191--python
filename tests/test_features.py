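"""Feature mappings, table assembly and k-nn imputation."""

import numpy as np
import pandas as pd
import pytest

from exhypo import features as feat
from exhypo import pipeline


class TestBorgToIntensity:
    @pytest.mark.parametrize(
        "borg,expected",
        [(6, "light"), (11, "light"), (12, "moderate"), (14, "moderate"),
         (15, "vigorous"), (20, "vigorous")],
    )
    def test_thresholds(self, borg, expected):
        assert feat.borg_to_intensity(borg) == expected

    @pytest.mark.parametrize("bad", [5, 21, "x", None])
    def test_out_of_range_becomes_missing(self, bad):
        assert feat.borg_to_intensity(bad) is np.nan or np.isnan(feat.borg_to_intensity(bad))


class TestTimeOfDay:
    @pytest.mark.parametrize(
        "hhmm,expected",
        [("05:00", "morning"), ("11:59", "morning"), ("12:00", "afternoon"),
         ("16:59", "afternoon"), ("17:00", "evening"), ("03:00", "evening"),
         ("04:59", "evening")],
    )
    def test_bins(self, hhmm, expected):
        t = pd.Timestamp(f"2023-01-01 {hhmm}")
        assert feat.time_of_day(t) == expected


class TestMapExerciseType:
    @pytest.mark.parametrize(
        "label,expected",
        [("running", "aerobic"), ("Weightlifting", "anaerobic"),
         ("CIRCUIT TRAINING", "mixed")],
    )
    def test_casefolded_lookup(self, label, expected):
        assert feat.map_exercise_type(label) == expected

    def test_unmapped_is_missing(self):
        assert np.isnan(feat.map_exercise_type("underwater basket weaving"))


class TestAssemble:
    def test_row_count_matches_included_bouts(self, small_cohort, small_table):
        table, qc = small_table
        assert len(table) == int(qc["included"].sum())

    def test_thirteen_candidate_variables_present_after_expansion(self, small_table):
        table, _ = small_table
        expanded = feat.dummy_expand(table)
        for col in feat.CANDIDATE_FEATURES:
            assert col in expanded.columns, col

    def test_missing_weight_propagates_to_iob_per_kg(self, small_cohort):
        participants = small_cohort.participants.copy()
        participants.loc[:, "weight_kg"] = np.nan
        table, _ = pipeline.preprocess(
            participants, small_cohort.series, small_cohort.boluses, small_cohort.bouts
        )
        assert table["iob_per_kg"].isna().all()
        assert table["starting_glucose"].notna().mean() > 0.9

    def test_missing_metadata_is_an_error(self, small_cohort):
        participants = small_cohort.participants.iloc[:-5]
        with pytest.raises(ValueError, match="no metadata"):
            pipeline.preprocess(
                participants, small_cohort.series, small_cohort.boluses, small_cohort.bouts
            )

    def test_deterministic(self, small_cohort, small_table):
        table, _ = small_table
        table2, _ = pipeline.preprocess(
            small_cohort.participants,
            small_cohort.series,
            small_cohort.boluses,
            small_cohort.bouts,
        )
        pd.testing.assert_frame_equal(table, table2)


def _toy_table(n=50, seed=0, mask=5):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "starting_glucose": rng.uniform(4, 14, n),
            "duration_min": rng.uniform(10, 120, n),
            "age_years": rng.uniform(15, 70, n),
            "trend": rng.choice(["falling", "stable", "rising"], n),
            "label": rng.integers(0, 2, n),
        }
    )
    masked = []
    for i in range(mask):
        col = ["starting_glucose", "age_years", "trend"][i % 3]
        row = int(rng.integers(0, n))
        masked.append((row, col, df.loc[row, col]))
        df.loc[row, col] = np.nan
    return df, masked


def _brute_force_knn(df, row, col, k, cont_cols):
    """Independent exhaustive-distance k-nn for one missing cell."""
    mu = df[cont_cols].mean()
    sd = df[cont_cols].std(ddof=0).replace(0, 1.0)
    z = (df[cont_cols] - mu) / sd
    target = z.loc[row]
    dists = []
    for j in z.index:
        if j == row:
            continue
        mutual = target.notna() & z.loc[j].notna()
        if not mutual.any():
            dists.append((np.inf, j))
            continue
        diff = (target[mutual] - z.loc[j][mutual]).to_numpy()
        dists.append((np.sqrt((diff**2).sum() / mutual.sum()), j))
    dists.sort(key=lambda t: t[0])
    donors = [j for d, j in dists if not pd.isna(df.loc[j, col]) and np.isfinite(d)][:k]
    if col in cont_cols:
        return df.loc[donors, col].mean()
    votes = df.loc[donors, col].value_counts()
    top = votes[votes == votes.max()]
    if len(top) == 1:
        return top.index[0]
    return df[col].value_counts().index[0]


class TestKnnImputation:
    CONT = ("starting_glucose", "duration_min", "age_years")
    CAT = ("trend",)

    def _imputer(self, k):
        return feat.KnnImputer(k=k, continuous=self.CONT, categorical=self.CAT)

    def test_complete_table_returned_unchanged(self):
        df, _ = _toy_table(mask=0)
        out = self._imputer(5).fit(df).transform(df)
        pd.testing.assert_frame_equal(out, df)

    def test_exact_duplicate_donor_with_k1(self):
        df = pd.DataFrame(
            {
                "starting_glucose": [7.0, 7.0, 12.0],
                "duration_min": [30.0, 30.0, 90.0],
                "age_years": [40.0, np.nan, 70.0],
                "trend": ["stable", "stable", "rising"],
                "label": [0, 1, 0],
            }
        )
        out = self._imputer(1).fit(df).transform(df)
        assert out.loc[1, "age_years"] == pytest.approx(40.0)

    def test_observed_cells_untouched(self):
        df, masked = _toy_table()
        out = self._imputer(5).fit(df).transform(df)
        observed = df.notna()
        for col in ("starting_glucose", "duration_min", "age_years", "trend"):
            same = out.loc[observed[col], col] == df.loc[observed[col], col]
            assert same.all()

    def test_matches_exhaustive_distance_oracle(self):
        """Imputed values equal an independently coded brute-force k-nn on a
        50-row fixture with 5 masked cells."""
        df, masked = _toy_table(n=50, seed=1, mask=5)
        out = self._imputer(5).fit(df).transform(df)
        cont = list(self.CONT)
        for row, col, _orig in masked:
            expected = _brute_force_knn(df, row, col, 5, cont)
            got = out.loc[row, col]
            if col in cont:
                assert got == pytest.approx(expected), (row, col)
            else:
                assert got == expected, (row, col)

    def test_label_never_used_or_imputed(self):
        df, _ = _toy_table()
        df.loc[3, "label"] = np.nan
        out = self._imputer(5).fit(df).transform(df)
        assert np.isnan(out.loc[3, "label"])

    def test_all_missing_feature_is_error(self):
        df, _ = _toy_table(mask=0)
        df["age_years"] = np.nan
        with pytest.raises(ValueError, match="missing in every"):
            self._imputer(5).fit(df)

    def test_agrees_with_sklearn_on_continuous_only(self):
        """Cross-check against sklearn's KNNImputer on standardised,
        fully-continuous data with a single missing cell."""
        from sklearn.impute import KNNImputer as SkKNN

        df, _ = _toy_table(n=30, seed=2, mask=0)
        df.loc[4, "starting_glucose"] = np.nan
        cont = list(self.CONT)
        out = self._imputer(5).fit(df).transform(df)
        mu, sd = df[cont].mean(), df[cont].std(ddof=0)
        z = (df[cont] - mu) / sd
        sk = SkKNN(n_neighbors=5).fit_transform(z)
        expected = sk[4, 0] * sd.iloc[0] + mu.iloc[0]
        assert out.loc[4, "starting_glucose"] == pytest.approx(expected, rel=1e-6)
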