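"""Shared fixtures: small synthetic datasets and fitted ensemble members.

Everything is generated programmatically with fixed seeds; the "small"
fixtures keep per-test cost to seconds, while ``driver_run`` reproduces
the full study conditions (10 covariates, 2 true drivers, 500 presences,
50 balanced bootstraps, all three learner families) once per session for
the recovery and goodness-of-fit checks.
"""

from __future__ import annotations

import warnings

import pytest

from icehab import (
    SimulationConfig,
    draw_bootstrap,
    evaluate_members,
    make_holdout,
    simulate_dataset,
)
from icehab.importance import aggregate_importance, importance_records
from icehab.models import HabitatEnsemble, LearnerSpec, tune_and_fit

TINY_GRIDS = {
    "RF": {"max_features": ["sqrt"], "n_estimators": [25]},
    "BRT": {"learning_rate": [0.1], "max_depth": [1], "n_estimators": [25]},
    "MAXENT": {"regularization": [1.0]},
}

RUN_GRIDS = {
    "RF": {"max_features": ["sqrt"], "n_estimators": [100]},
    "BRT": {"learning_rate": [0.1], "max_depth": [3], "n_estimators": [100]},
    "MAXENT": {"regularization": [1.0]},
}


@pytest.fixture(scope="session")
def small_dataset():
    """120 presences vs 600 absences, 5 covariates, one strong driver."""
    cfg = SimulationConfig(
        n_presence=120,
        n_absence=600,
        covariate_names=("x0", "x1", "x2", "x3", "x4"),
        driver_coefficients={"x0": 2.5},
        intercept=-1.0,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return make_holdout(small_dataset.table, presence_fraction=0.2, seed=1)


@pytest.fixture(scope="session")
def small_bootstrap(small_split):
    return draw_bootstrap(small_split.train, bootstrap_id=0, seed=2)


@pytest.fixture(scope="session")
def small_members(small_bootstrap):
    """One tuned member per learner family on the same balanced bootstrap."""
    members = {}
    for lt in ("RF", "BRT", "MAXENT"):
        spec = LearnerSpec(lt, grid=dict(TINY_GRIDS[lt]), maxent_features=("linear", "quadratic"))
        members[lt] = tune_and_fit(small_bootstrap, spec, seed=7)
    return members


@pytest.fixture(scope="session")
def driver_run():
    """Full study conditions: 2 drivers among 10 covariates, 50 bootstraps.

    Returns the dataset, split, fitted ensemble (150 members), long
    importance records, their aggregate, and the hold-out evaluation.
    """
    cfg = SimulationConfig(
        n_presence=500,
        n_absence=5000,
        covariate_names=tuple(f"x{i}" for i in range(10)),
        driver_coefficients={"x0": 2.0, "x1": -1.5},
        intercept=-2.0,
        seed=11,
    )
    ds = simulate_dataset(cfg)
    split = make_holdout(ds.table, presence_fraction=0.2, seed=2)
    ens = HabitatEnsemble(
        n_bootstraps=50,
        grids=RUN_GRIDS,
        maxent_features=("linear", "quadratic"),
        random_state=3,
    ).fit(split.train)
    samples = {s.bootstrap_id: s for s in ens.bootstraps_}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = importance_records(ens.members_, samples=samples, n_permutations=5, seed=4)
    summary = aggregate_importance(records)
    evaluation = evaluate_members(ens.members_, split.test)
    return {
        "dataset": ds,
        "split": split,
        "ensemble": ens,
        "records": records,
        "summary": summary,
        "evaluation": evaluation,
    }
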