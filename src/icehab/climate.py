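"""Expert climate-change scores and the change importance product (CIP).

Each rater assigns every environmental variable an integer score from 0
(no expected change under climate change) to 3 (high expected change);
scores are averaged across raters into a per-variable *climate change
score*. Multiplying that score by a model's mean proportional importance
for the variable yields the change importance product -- an index that is
large only for variables that are both influential on breeding habitat
and likely to change. Variables are ranked by the mean CIP across the
three learner families, in descending order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "load_score_sheet",
    "validate_score_sheet",
    "average_scores",
    "change_importance_product",
    "rank_report",
]


def load_score_sheet(path: str | Path) -> pd.DataFrame:
    """Read a rater x variable score CSV (first column = rater id)."""
    sheet = pd.read_csv(path, index_col=0)
    return validate_score_sheet(sheet)


def validate_score_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if sheet.empty:
        raise ValueError("score sheet is empty")
    if sheet.isna().any().any():
        bad = [c for c in sheet.columns if sheet[c].isna().any()]
        raise ValueError(f"every variable must be scored by every rater; missing in {bad}")
    vals = sheet.to_numpy()
    if not np.all(np.isin(vals, [0, 1, 2, 3])):
        raise ValueError("scores must be integers in {0, 1, 2, 3}")
    return sheet


def average_scores(sheet: pd.DataFrame) -> pd.Series:
    """Per-variable climate change score: arithmetic mean across raters."""
    validate_score_sheet(sheet)
    return sheet.mean(axis=0).rename("climate_change_score")


def change_importance_product(
    importance_summary: pd.DataFrame,
    scores: pd.Series | pd.DataFrame,
) -> pd.DataFrame:
    """CIP records: climate change score x mean proportional importance.

    ``importance_summary`` is the aggregated importance table (columns
    learner_type, variable, mean_proportional_importance); ``scores`` is
    either a per-variable score Series or a raw rater sheet (averaged
    here). Every variable carrying importance must have a score. Each row
    gets the product for its learner family, the unweighted mean product
    across families (``overall_mean_product``) and a dense descending rank
    on that mean.
    """
    if isinstance(scores, pd.DataFrame):
        scores = average_scores(scores)
    missing = sorted(set(importance_summary["variable"]) - set(scores.index))
    if missing:
        raise ValueError(f"no climate change score for variables: {missing}")
    out = importance_summary.copy()
    out["climate_change_score"] = out["variable"].map(scores).astype(float)
    out["product"] = out["climate_change_score"] * out["mean_proportional_importance"]
    overall = out.groupby("variable")["product"].mean().rename("overall_mean_product")
    out = out.merge(overall, on="variable")
    out["rank"] = (
        out["overall_mean_product"].rank(method="dense", ascending=False).astype(int)
    )
    cols = [
        "variable",
        "learner_type",
        "climate_change_score",
        "mean_proportional_importance",
        "product",
        "overall_mean_product",
        "rank",
    ]
    return out[cols].sort_values(["rank", "variable", "learner_type"]).reset_index(drop=True)


def rank_report(records: pd.DataFrame) -> pd.DataFrame:
    """One row per variable, ranked by overall mean CIP, ties flagged.

    Ties on the overall mean product share a rank, are ordered
    alphabetically, and are marked in the ``tied`` column.
    """
    if records.empty:
        raise ValueError("no CIP records to rank")
    wide = (
        records.pivot_table(index="variable", columns="learner_type", values="product")
        .add_prefix("product_")
        .reset_index()
    )
    per_var = records.drop_duplicates("variable")[
        ["variable", "climate_change_score", "overall_mean_product", "rank"]
    ]
    out = per_var.merge(wide, on="variable")
    out = out.sort_values(["rank", "variable"], kind="stable").reset_index(drop=True)
    counts = out["overall_mean_product"].round(12).value_counts()
    out["tied"] = out["overall_mean_product"].round(12).map(counts) > 1
    return out
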