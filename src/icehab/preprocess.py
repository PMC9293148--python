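"""Collinearity screening, balanced hold-out and balanced bootstraps.

Environmental covariates in ice-habitat studies are heavily collinear
(ice metrics derive from the same sensors, distances share geometry), so
before any model fitting the covariate set is screened by variance
inflation factor, VIF_j = 1 / (1 - R^2_j) with R^2_j from an OLS
regression of covariate j on all the others; variables with VIF above a
threshold (default 10) are removed one at a time, worst first.

Presence records are far rarer than absences, so evaluation and training
are balanced explicitly: the hold-out test set takes a fraction of the
presences plus an equal number of absences, and each bootstrap training
replicate contains *all* remaining presences plus an equal-size random
sample of absences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "METADATA_COLUMNS",
    "VIFReport",
    "DataSplit",
    "BootstrapSample",
    "covariate_columns",
    "load_occurrence",
    "compute_vif",
    "filter_by_vif",
    "VIFFilter",
    "make_holdout",
    "draw_bootstrap",
]

#: Occurrence-table columns that are not covariates.
METADATA_COLUMNS = ("id", "presence")

_UNBOUNDED_TOL = 1e-12  # 1 - R^2 below this is treated as perfect dependence


def covariate_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def load_occurrence(path: str | Path) -> pd.DataFrame:
    """Read and validate an occurrence CSV (columns: id, presence, covariates)."""
    table = pd.read_csv(path)
    return validate_occurrence(table)


def validate_occurrence(table: pd.DataFrame) -> pd.DataFrame:
    for col in METADATA_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"occurrence table missing required column {col!r}")
    if not set(table["presence"].unique()) <= {0, 1}:
        raise ValueError("presence column must be strictly binary (0/1)")
    covs = covariate_columns(table)
    if len(covs) != len(set(covs)):
        raise ValueError("covariate names must be unique")
    if table[covs].isna().any().any():
        bad = [c for c in covs if table[c].isna().any()]
        raise ValueError(f"missing covariate values in columns {bad}")
    return table


@dataclass
class VIFReport:
    """Outcome of (iterative) VIF screening.

    ``vif`` holds the final per-variable VIF of the retained set (np.inf
    flags perfect linear dependence); ``removed`` lists each discarded
    variable with its VIF at the moment of removal, in removal order.
    """

    vif: pd.Series
    retained: list[str]
    removed: list[tuple[str, float]] = field(default_factory=list)
    threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": v, "vif": float(x), "retained": True} for v, x in self.vif.items()]
        rows += [{"variable": v, "vif": float(x), "retained": False} for v, x in self.removed]
        return pd.DataFrame(rows)


def _vif_values(X: np.ndarray, names: Sequence[str]) -> pd.Series:
    n, p = X.shape
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant covariate column(s) {bad}: VIF undefined")
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        y = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        one_minus_r2 = ss_res / ss_tot
        out[j] = np.inf if one_minus_r2 < _UNBOUNDED_TOL else 1.0 / one_minus_r2
    return pd.Series(out, index=list(names), name="vif")


def compute_vif(table: pd.DataFrame, variables: Sequence[str] | None = None) -> pd.Series:
    """Per-covariate variance inflation factors.

    Accepts a full occurrence table (id/presence columns are ignored) or a
    bare covariate frame. Perfect linear dependence is reported as
    ``np.inf`` rather than an overflowed float.
    """
    if variables is None:
        variables = covariate_columns(table)
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("VIF needs at least 2 covariates")
    X = table[variables].to_numpy(dtype=float)
    if X.shape[0] < len(variables) + 1:
        raise ValueError("VIF needs at least covariates+1 records")
    return _vif_values(X, variables)


def filter_by_vif(table: pd.DataFrame, threshold: float = 10.0) -> VIFReport:
    """Stepwise VIF screening: drop the worst variable, recompute, repeat.

    Removal continues until every remaining VIF is <= ``threshold`` or
    fewer than two variables remain (then screening stops with a warning).
    Ties on the maximum VIF are broken alphabetically so the procedure is
    deterministic.
    """
    remaining = covariate_columns(table)
    removed: list[tuple[str, float]] = []
    while True:
        if len(remaining) < 2:
            warnings.warn("fewer than 2 covariates remain; VIF screening stopped", stacklevel=2)
            vif = pd.Series(np.ones(len(remaining)), index=remaining, name="vif")
            break
        vif = compute_vif(table, remaining)
        worst = vif.max()
        if worst <= threshold:
            break
        # alphabetical tie-break among variables sharing the maximum
        candidates = sorted(vif.index[vif == worst])
        victim = candidates[0]
        removed.append((victim, float(worst)))
        remaining = [v for v in remaining if v != victim]
    return VIFReport(vif=vif, retained=list(remaining), removed=removed, threshold=threshold)


class VIFFilter(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping stepwise VIF screening.

    Parameters
    ----------
    threshold:
        Maximum admissible VIF; variables above it are removed iteratively
        (worst first, alphabetical tie-break).

    Attributes
    ----------
    vif_ : pd.Series
        Final VIF of the retained variables.
    retained_ : list of str
    removed_ : list of (str, float)
        Removal order with the VIF at removal.
    """

    def __init__(self, threshold: float = 10.0):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "VIFFilter":
        X = self._as_frame(X)
        report = filter_by_vif(X, threshold=self.threshold)
        self.vif_ = report.vif
        self.retained_ = report.retained
        self.removed_ = report.removed
        self.feature_names_in_ = np.asarray(covariate_columns(X), dtype=object)
        self.n_features_in_ = len(self.feature_names_in_)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "retained_"):
            raise AttributeError("VIFFilter is not fitted yet")
        X = self._as_frame(X)
        keep = [c for c in X.columns if c in METADATA_COLUMNS] + self.retained_
        return X[keep]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.retained_, dtype=object)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


@dataclass
class DataSplit:
    """Disjoint train/test partition with a class-balanced test set."""

    train: pd.DataFrame
    test: pd.DataFrame
    seed: int | None = None

    def membership(self) -> pd.DataFrame:
        return pd.concat(
            [
                pd.DataFrame({"record_id": self.train["id"], "role": "train"}),
                pd.DataFrame({"record_id": self.test["id"], "role": "test"}),
            ],
            ignore_index=True,
        )


def make_holdout(
    table: pd.DataFrame,
    presence_fraction: float = 0.2,
    seed: int | None = None,
    n_test_presence: int | None = None,
) -> DataSplit:
    """Balanced hold-out split: a fraction of presences + equal absences.

    ``floor(presence_fraction * total presences)`` presence records are
    drawn uniformly at random into the test set, together with an equal
    number of absences drawn uniformly across the whole table; everything
    else is training data. ``n_test_presence`` overrides the fraction with
    an explicit presence count.
    """
    if n_test_presence is None:
        if not 0 <= presence_fraction < 1:
            raise ValueError("presence_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pres = table.index[table["presence"] == 1].to_numpy()
    absn = table.index[table["presence"] == 0].to_numpy()
    k = int(n_test_presence) if n_test_presence is not None else int(np.floor(presence_fraction * len(pres)))
    if k > len(pres):
        raise ValueError(f"requested {k} test presences but only {len(pres)} available")
    if k > len(absn):
        raise ValueError(f"balancing needs {k} absences but only {len(absn)} available")
    test_p = rng.choice(pres, size=k, replace=False)
    test_a = rng.choice(absn, size=k, replace=False)
    test_idx = np.concatenate([test_p, test_a])
    mask = table.index.isin(test_idx)
    test = table.loc[mask].reset_index(drop=True)
    train = table.loc[~mask].reset_index(drop=True)
    return DataSplit(train=train, test=test, seed=seed)


@dataclass
class BootstrapSample:
    """One balanced training replicate: all presences + equal sampled absences."""

    bootstrap_id: int
    records: pd.DataFrame


def draw_bootstrap(train: pd.DataFrame, bootstrap_id: int, seed: int | None = None) -> BootstrapSample:
    """Draw one balanced bootstrap from the training table.

    Every training presence is included exactly once; absences are sampled
    uniformly without replacement when the absence pool is at least as
    large as the presence count, with replacement otherwise. The returned
    sample therefore always has a 1:1 class ratio and size
    ``2 * n_presence``.
    """
    pres = train[train["presence"] == 1]
    absn = train[train["presence"] == 0]
    if len(pres) == 0 or len(absn) == 0:
        raise ValueError("bootstrap needs at least one presence and one absence")
    rng = np.random.default_rng([seed if seed is not None else 0, bootstrap_id])
    replace = len(absn) < len(pres)
    pick = rng.choice(absn.index.to_numpy(), size=len(pres), replace=replace)
    records = pd.concat([pres, absn.loc[pick]], ignore_index=True)
    return BootstrapSample(bootstrap_id=bootstrap_id, records=records)
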