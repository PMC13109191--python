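"""Shared fixtures: synthetic cohorts at two scales.

The large cohort (~5,500 included bouts) backs the statistical checks —
signal recovery, leakage, calibration — and is built once per session; the
small cohort keeps structural tests fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from exhypo import model, pipeline, simulate
from exhypo.cgm import GlucoseSeries


@pytest.fixture(scope="session")
def big_cohort():
    cfg = simulate.SimConfig(n_participants=300, seed=11)
    return simulate.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def big_table(big_cohort):
    table, qc = pipeline.preprocess(
        big_cohort.participants,
        big_cohort.series,
        big_cohort.boluses,
        big_cohort.bouts,
    )
    return table, qc


@pytest.fixture(scope="session")
def big_fold_data(big_table):
    table, _ = big_table
    plan = model.make_folds(table, k=10, seed=0)
    return plan, model.prepare_fold_data(table, plan)


@pytest.fixture(scope="session")
def simplified_ensemble(big_table, big_fold_data):
    from exhypo.features import SIMPLIFIED_FEATURES

    table, _ = big_table
    plan, fold_data = big_fold_data
    return model.train_cv(table, plan, SIMPLIFIED_FEATURES, fold_data=fold_data, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = simulate.SimConfig(n_participants=30, days=10, seed=5)
    return simulate.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    table, qc = pipeline.preprocess(
        small_cohort.participants,
        small_cohort.series,
        small_cohort.boluses,
        small_cohort.bouts,
    )
    return table, qc


def make_series(
    pid: str = "P1",
    start: str = "2023-01-01 08:00",
    n: int = 50,
    interval: float = 5.0,
    values=None,
) -> GlucoseSeries:
    """Evenly sampled helper series for unit tests."""
    times = pd.date_range(start, periods=n, freq=f"{interval}min")
    if values is None:
        values = np.full(n, 7.0)
    return GlucoseSeries(pid, times, np.asarray(values, dtype=float))


@pytest.fixture
def series_factory():
    return make_series
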