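"""Per-member variable importance and its cross-model normalization.

The three learner families expose importance differently: permutation
importance (metric drop under shuffling one covariate) for the random
forest and Maxent members, and split-gain percentage contribution
("relative influence") for the boosted trees. To make them comparable,
each member's raw importances are converted to *proportional* importance:
negatives clipped to zero, then divided by the sum, so every member
contributes a point on the simplex. Proportions are finally averaged per
(learner family, variable) across bootstraps.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor

from .metrics import auc
from .models import FittedMember, predict
from .preprocess import BootstrapSample, covariate_columns

__all__ = [
    "permutation_importance",
    "brt_relative_influence",
    "proportional_importance",
    "member_importance",
    "importance_records",
    "aggregate_importance",
]


def _resolve_metric(metric) -> Callable:
    if callable(metric):
        return metric
    if metric == "auc":
        return auc
    raise ValueError(f"unknown metric {metric!r}")


def permutation_importance(
    member: FittedMember,
    data: pd.DataFrame,
    metric="auc",
    n_permutations: int = 5,
    seed: int | None = None,
) -> pd.Series:
    """Raw permutation importance per covariate.

    importance(v) = baseline metric - mean metric over ``n_permutations``
    independent shuffles of column v. The default metric is AUC evaluated
    on ``data`` (by convention the member's own bootstrap records). With
    ``n_permutations=0`` every importance is exactly 0 (identity
    permutation degenerate path).
    """
    metric_fn = _resolve_metric(metric)
    y = data["presence"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("importance metric undefined on single-class data")
    X = data[list(member.feature_names)]
    variables = list(member.feature_names)
    if n_permutations == 0:
        return pd.Series(np.zeros(len(variables)), index=variables, name="raw_importance")
    rng = np.random.default_rng(seed)
    baseline = metric_fn(y, predict(member, X))
    out = {}
    for v in variables:
        drops = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[v] = rng.permutation(Xp[v].to_numpy())
            drops.append(baseline - metric_fn(y, predict(member, Xp)))
        out[v] = float(np.mean(drops))
    return pd.Series(out, name="raw_importance")


def brt_relative_influence(member) -> pd.Series:
    """Split-gain percentage contribution of each covariate in a BRT member.

    For every split node in every tree of every boosting stage, the
    squared-error reduction is
    ``w_node * impurity_node - w_left * impurity_left - w_right * impurity_right``
    (w = weighted node sample count); gains are summed per splitting
    covariate across the whole ensemble and normalized to percentages
    summing to 100.
    """
    model = member.model if isinstance(member, FittedMember) else member
    if not isinstance(model, (GradientBoostingClassifier, GradientBoostingRegressor)):
        raise TypeError("relative influence requires a boosted-tree member with split records")
    if isinstance(member, FittedMember):
        names: Sequence[str] = member.feature_names
    else:
        names = getattr(model, "feature_names_in_", [f"x{j}" for j in range(model.n_features_in_)])
    gains = np.zeros(len(names))
    for stage in model.estimators_.ravel():
        t = stage.tree_
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:  # leaf
                continue
            gain = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            )
            gains[t.feature[node]] += max(gain, 0.0)
    total = gains.sum()
    if total == 0:
        raise ValueError("boosted ensemble recorded no split gain")
    return pd.Series(100.0 * gains / total, index=list(names), name="raw_importance")


def proportional_importance(raw: pd.Series) -> pd.Series:
    """Normalize raw importances onto the simplex.

    Negative raw values (possible under permutation importance) are
    clipped to 0 before dividing by the sum; an all-zero vector is
    rejected because no proportion is defined.
    """
    clipped = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    total = clipped.sum()
    if total <= 0:
        raise ValueError("all raw importances are <= 0; proportional importance undefined")
    return pd.Series(clipped / total, index=raw.index, name="proportional_importance")


def member_importance(
    member: FittedMember,
    data: pd.DataFrame | None = None,
    metric="auc",
    n_permutations: int = 5,
    seed: int | None = None,
) -> pd.Series:
    """Raw importance for one member, dispatched on learner family.

    BRT members use split-gain relative influence; RF and MAXENT members
    use permutation importance on ``data``.
    """
    if member.learner_type == "BRT":
        return brt_relative_influence(member)
    if data is None:
        raise ValueError("permutation importance needs evaluation data")
    return permutation_importance(member, data, metric=metric, n_permutations=n_permutations, seed=seed)


def importance_records(
    members: Iterable[FittedMember],
    samples: dict[int, BootstrapSample] | None = None,
    metric="auc",
    n_permutations: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format importance table over an ensemble.

    One row per (learner_type, bootstrap_id, variable) with raw and
    proportional importance. ``samples`` maps bootstrap_id to the sample
    whose records are used for permutation importance (in-bag evaluation).

    A member whose raw importances are all zero (e.g. a fully shrunk
    Maxent member predicting a constant) carries no ranking information;
    it contributes uniform proportions, with a warning, rather than
    aborting the whole ensemble.
    """
    rows = []
    for k, member in enumerate(members):
        data = samples[member.bootstrap_id].records if samples else None
        mseed = None if seed is None else int(np.random.default_rng([seed, k]).integers(2**31))
        raw = member_importance(member, data, metric=metric, n_permutations=n_permutations, seed=mseed)
        try:
            prop = proportional_importance(raw)
        except ValueError:
            warnings.warn(
                f"{member.learner_type} bootstrap {member.bootstrap_id}: all raw importances "
                "<= 0; assigning uniform proportions",
                stacklevel=2,
            )
            prop = pd.Series(np.full(len(raw), 1.0 / len(raw)), index=raw.index)
        for v in raw.index:
            rows.append(
                {
                    "learner_type": member.learner_type,
                    "bootstrap_id": member.bootstrap_id,
                    "variable": v,
                    "raw_importance": float(raw[v]),
                    "proportional_importance": float(prop[v]),
                }
            )
    return pd.DataFrame(rows)


def aggregate_importance(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of proportional importance per (learner_type, variable).

    SD is the sample standard deviation across bootstraps (0 for a single
    bootstrap). Output is long format, one row per group, sorted by
    learner type then descending mean.
    """
    if records.empty:
        raise ValueError("no importance records to aggregate")
    g = records.groupby(["learner_type", "variable"])["proportional_importance"]
    out = g.agg(mean_proportional_importance="mean", sd_proportional_importance="std", n_bootstraps="count")
    out["sd_proportional_importance"] = out["sd_proportional_importance"].fillna(0.0)
    out = out.reset_index()
    return out.sort_values(
        ["learner_type", "mean_proportional_importance"], ascending=[True, False]
    ).reset_index(drop=True)
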