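"""The three-member habitat ensemble: random forest, boosted trees, Maxent.

Each balanced bootstrap sample is fed to three learner families -- a
random forest (RF), a boosted regression tree (BRT) and the
presence/background maximum-entropy model (MAXENT) -- and each learner is
tuned per bootstrap by grid search: the bootstrap's records are randomly
partitioned into k folds of near-equal size (default k = 10), out-of-fold
probability predictions are pooled across folds, and the candidate with
the highest R^2 of those pooled predictions against the 0/1 labels is
refit on the whole sample. Ties go to the simpler candidate (fewer trees,
shallower interaction depth, larger regularization), then to declaration
order.

The tree learners are backed by scikit-learn; the Maxent learner is the
in-repo :class:`icehab.maxent.MaxentClassifier`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from .maxent import MaxentClassifier
from .metrics import r_squared
from .preprocess import BootstrapSample, covariate_columns, draw_bootstrap

__all__ = [
    "LEARNER_TYPES",
    "LearnerSpec",
    "FittedMember",
    "default_grid",
    "tune_and_fit",
    "predict",
    "HabitatEnsemble",
]

LEARNER_TYPES = ("RF", "BRT", "MAXENT")


def default_grid(learner_type: str, n_features: int | None = None) -> dict[str, list]:
    """Conventional tuning grid for one learner family.

    RF varies the number of covariates tried per split over
    {ceil(sqrt(p)), ceil(p/3), p} at 500 trees; BRT varies learning rate,
    interaction depth and tree count; MAXENT varies the regularization
    multiplier. Any grid can be overridden per run.
    """
    lt = learner_type.upper()
    if lt == "RF":
        if n_features is None:
            mf: list[Any] = ["sqrt", 0.3333, 1.0]
        else:
            mf = sorted({math.ceil(math.sqrt(n_features)), math.ceil(n_features / 3), n_features})
        return {"max_features": mf, "n_estimators": [500]}
    if lt == "BRT":
        return {"learning_rate": [0.01, 0.1], "max_depth": [1, 3], "n_estimators": [100, 500]}
    if lt == "MAXENT":
        return {"regularization": [0.5, 1.0, 2.0]}
    raise ValueError(f"unknown learner type {learner_type!r}")


@dataclass
class LearnerSpec:
    """One learner family plus its tuning protocol."""

    learner_type: str
    grid: dict[str, list] = field(default_factory=dict)
    cv_folds: int = 10
    selection_metric: str = "cv_r_squared"
    maxent_features: tuple[str, ...] = ("linear", "quadratic", "hinge")
    maxent_hinge_knots: int = 5

    def __post_init__(self) -> None:
        self.learner_type = self.learner_type.upper()
        if self.learner_type not in LEARNER_TYPES:
            raise ValueError(f"learner_type must be one of {LEARNER_TYPES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.grid:
            self.grid = default_grid(self.learner_type)
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid lists must be non-empty")

    def candidates(self) -> list[dict[str, Any]]:
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]

    def build(self, params: Mapping[str, Any], seed: int) -> BaseEstimator:
        if self.learner_type == "RF":
            return RandomForestClassifier(random_state=seed, **params)
        if self.learner_type == "BRT":
            return GradientBoostingClassifier(random_state=seed, **params)
        return MaxentClassifier(
            features=self.maxent_features,
            n_hinge_knots=self.maxent_hinge_knots,
            **params,
        )

    def complexity(self, params: Mapping[str, Any]) -> tuple:
        """Sort key: smaller = simpler, used to break CV-score ties."""
        if self.learner_type == "MAXENT":
            return (-float(params.get("regularization", 1.0)),)
        return (
            params.get("n_estimators", 0),
            params.get("max_depth", 0),
            params.get("learning_rate", 0.0),
        )


@dataclass
class FittedMember:
    """One fitted ensemble member (learner family x bootstrap)."""

    learner_type: str
    bootstrap_id: int
    params: dict[str, Any]
    cv_score: float
    model: BaseEstimator
    feature_names: tuple[str, ...]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict(self, X)


def _cv_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into k folds whose sizes differ by at most one."""
    perm = rng.permutation(n)
    return [f for f in np.array_split(perm, k) if len(f)]


def tune_and_fit(
    sample: BootstrapSample,
    spec: LearnerSpec,
    seed: int = 0,
) -> FittedMember:
    """Grid-tune one learner on one balanced bootstrap and refit the winner.

    For every grid candidate, out-of-fold probability predictions from a
    random ``cv_folds``-fold partition are pooled and scored with
    R^2 = 1 - SS_res/SS_tot against the binary labels; the best candidate
    is refit on the full sample. Fold assignment, tree randomness and the
    refit all derive from ``seed`` and the bootstrap id, so a member is
    bit-reproducible.
    """
    df = sample.records
    features = covariate_columns(df)
    X = df[features]
    y = df["presence"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("bootstrap sample is single-class; cannot fit")
    rng = np.random.default_rng([seed, sample.bootstrap_id, _stage_key(spec.learner_type)])
    fit_seed = int(rng.integers(2**31))
    folds = _cv_folds(len(df), spec.cv_folds, rng)

    best: tuple[float, tuple, int] | None = None  # (-score, complexity, index)
    best_params: dict[str, Any] | None = None
    best_score = -np.inf
    for idx, params in enumerate(spec.candidates()):
        oof = np.empty(len(df))
        ok = True
        for fold in folds:
            train_idx = np.setdiff1d(np.arange(len(df)), fold)
            est = spec.build(params, fit_seed)
            ytr = y[train_idx]
            if len(np.unique(ytr)) < 2:
                ok = False
                break
            est.fit(X.iloc[train_idx], ytr)
            oof[fold] = est.predict_proba(X.iloc[fold])[:, 1]
        if not ok:
            continue
        score = r_squared(y, oof)
        key = (-score, spec.complexity(params), idx)
        if best is None or key < best:
            best, best_params, best_score = key, params, score

    if best_params is None:
        raise RuntimeError("no grid candidate could be cross-validated")
    model = spec.build(best_params, fit_seed)
    model.fit(X, y)
    return FittedMember(
        learner_type=spec.learner_type,
        bootstrap_id=sample.bootstrap_id,
        params=dict(best_params),
        cv_score=float(best_score),
        model=model,
        feature_names=tuple(features),
    )


def _stage_key(learner_type: str) -> int:
    return LEARNER_TYPES.index(learner_type)


def predict(member: FittedMember, X: pd.DataFrame) -> np.ndarray:
    """Probability of presence from one member, validated against training names."""
    if isinstance(X, pd.DataFrame):
        missing = set(member.feature_names) - set(X.columns)
        if missing:
            raise ValueError(f"missing covariates {sorted(missing)}")
        extra = set(covariate_columns(X)) - set(member.feature_names)
        if extra:
            raise ValueError(f"unknown covariates {sorted(extra)}")
        X = X[list(member.feature_names)]
    p = member.model.predict_proba(X)[:, 1]
    return np.clip(p, 0.0, 1.0)


class HabitatEnsemble(ClassifierMixin, BaseEstimator):
    """Balanced-bootstrap ensemble over RF, BRT and Maxent learners.

    ``fit`` draws ``n_bootstraps`` balanced replicates from the training
    table (all presences + an equal random sample of absences each) and
    grid-tunes every requested learner family on every replicate, yielding
    ``n_bootstraps * len(learners)`` members. ``predict_proba`` averages
    the members' probability predictions.

    Parameters
    ----------
    learners : sequence of {"RF", "BRT", "MAXENT"}
    n_bootstraps : int
    grids : mapping learner_type -> grid dict, optional
        Defaults to :func:`default_grid` per family.
    cv_folds : int
    random_state : int

    Attributes
    ----------
    members_ : list of :class:`FittedMember`
    specs_ : the resolved :class:`LearnerSpec` per family
    feature_names_ : covariates seen during fit
    """

    def __init__(
        self,
        learners: Sequence[str] = LEARNER_TYPES,
        n_bootstraps: int = 500,
        grids: Mapping[str, dict] | None = None,
        cv_folds: int = 10,
        maxent_features: tuple[str, ...] = ("linear", "quadratic", "hinge"),
        maxent_hinge_knots: int = 5,
        random_state: int = 0,
    ):
        self.learners = learners
        self.n_bootstraps = n_bootstraps
        self.grids = grids
        self.cv_folds = cv_folds
        self.maxent_features = maxent_features
        self.maxent_hinge_knots = maxent_hinge_knots
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: Iterable[int] | None = None) -> "HabitatEnsemble":
        """Fit from an occurrence table (or a covariate frame plus labels y)."""
        table = self._as_table(X, y)
        features = covariate_columns(table)
        grids = dict(self.grids or {})
        self.specs_ = {
            lt.upper(): LearnerSpec(
                learner_type=lt,
                grid=grids.get(lt.upper(), default_grid(lt, len(features))),
                cv_folds=self.cv_folds,
                maxent_features=tuple(self.maxent_features),
                maxent_hinge_knots=self.maxent_hinge_knots,
            )
            for lt in self.learners
        }
        self.members_ = []
        self.bootstraps_ = []
        for b in range(self.n_bootstraps):
            sample = draw_bootstrap(table, bootstrap_id=b, seed=self.random_state)
            self.bootstraps_.append(sample)
            for spec in self.specs_.values():
                self.members_.append(tune_and_fit(sample, spec, seed=self.random_state))
        self.feature_names_ = tuple(features)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(features)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "members_"):
            raise AttributeError("HabitatEnsemble is not fitted yet")
        p1 = np.mean([predict(m, X) for m in self.members_], axis=0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    @staticmethod
    def _as_table(X, y) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame) and "presence" in X.columns:
            table = X.copy()
        else:
            if y is None:
                raise ValueError("y is required unless X is an occurrence table with a presence column")
            if not isinstance(X, pd.DataFrame):
                X = pd.DataFrame(np.asarray(X, dtype=float))
                X.columns = [f"x{j}" for j in X.columns]
            table = X.copy()
            table.insert(0, "presence", np.asarray(list(y), dtype=int))
        if "id" not in table.columns:
            table.insert(0, "id", [f"rec{k:06d}" for k in range(len(table))])
        return table
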