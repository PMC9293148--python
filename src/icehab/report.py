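"""Hold-out evaluation, partial dependence and the end-to-end pipeline.

``run_species_analysis`` executes the whole analysis for one species:
VIF screening -> balanced hold-out -> balanced bootstraps -> per-bootstrap
grid-tuned RF/BRT/Maxent members -> per-member variable importance ->
climate-score-weighted change importance product -> hold-out goodness of
fit (AUC and R^2 for every member) -> ensemble partial dependence with SD
pooled across all members of all learner families. Each stage is an
importable function, so a run can be re-entered at any stage with the
previous stage's outputs; a machine-readable manifest records counts,
seeds and table digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from .importance import aggregate_importance, importance_records
from .metrics import auc, r_squared
from .models import LEARNER_TYPES, FittedMember, HabitatEnsemble, predict
from .preprocess import (
    DataSplit,
    VIFReport,
    covariate_columns,
    filter_by_vif,
    load_occurrence,
    make_holdout,
    validate_occurrence,
)

__all__ = [
    "EvaluationResult",
    "PartialDependenceCurve",
    "AnalysisConfig",
    "ReportBundle",
    "evaluate_members",
    "partial_dependence",
    "run_species_analysis",
]

log = logging.getLogger("icehab")


@dataclass
class EvaluationResult:
    """Hold-out goodness of fit per learner family.

    ``per_member`` has one row per fitted member (learner_type,
    bootstrap_id, auc, r_squared); ``summary`` gives mean and SD per
    learner family for both metrics, mirroring the usual dual convention
    (AUC for binary accuracy, R^2 for continuous-score fit).
    """

    per_member: pd.DataFrame
    summary: pd.DataFrame


def evaluate_members(members: Sequence[FittedMember], test: pd.DataFrame) -> EvaluationResult:
    """Score every member on the balanced hold-out set (AUC and R^2)."""
    y = test["presence"].to_numpy()
    rows = []
    for m in members:
        p = predict(m, test)
        rows.append(
            {
                "learner_type": m.learner_type,
                "bootstrap_id": m.bootstrap_id,
                "auc": auc(y, p),
                "r_squared": r_squared(y, p),
            }
        )
    per_member = pd.DataFrame(rows)
    g = per_member.groupby("learner_type")[["auc", "r_squared"]]
    summary = g.agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary = summary.fillna(0.0).reset_index()
    return EvaluationResult(per_member=per_member, summary=summary)


@dataclass
class PartialDependenceCurve:
    """Ensemble partial dependence of presence probability on one covariate."""

    variable: str
    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    per_learner: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": self.variable, "grid": self.grid, "mean": self.mean, "sd": self.sd}
        )


def partial_dependence(
    members: Sequence[FittedMember],
    variable: str,
    data: pd.DataFrame,
    grid_size: int = 50,
) -> PartialDependenceCurve:
    """Partial dependence with SD pooled across models and bootstraps.

    For each grid value g (``grid_size`` evenly spaced points between the
    1st and 99th percentile of the observed covariate), every record's
    ``variable`` is set to g and each member's predictions are averaged
    over records; the curve is the mean of those per-member values, the
    band their SD across all members of all learner families.
    """
    if not members:
        raise ValueError("need at least one fitted member")
    if variable not in data.columns:
        raise ValueError(f"variable {variable!r} not in data")
    x = data[variable].to_numpy(dtype=float)
    lo, hi = np.percentile(x, [1, 99])
    if hi <= lo:
        lo, hi = x.min(), x.max()
    grid = np.linspace(lo, hi, grid_size)
    X = data[list(members[0].feature_names)].copy()
    per_member = np.empty((len(members), grid_size))
    for gi, g in enumerate(grid):
        Xg = X.copy()
        Xg[variable] = g
        for mi, m in enumerate(members):
            per_member[mi, gi] = predict(m, Xg).mean()
    mean = per_member.mean(axis=0)
    sd = per_member.std(axis=0)  # population SD: one member -> 0
    rows = []
    for lt in sorted({m.learner_type for m in members}):
        idx = [i for i, m in enumerate(members) if m.learner_type == lt]
        rows.append(
            pd.DataFrame(
                {
                    "learner_type": lt,
                    "grid": grid,
                    "mean": per_member[idx].mean(axis=0),
                    "sd": per_member[idx].std(axis=0),
                }
            )
        )
    return PartialDependenceCurve(
        variable=variable, grid=grid, mean=mean, sd=sd, per_learner=pd.concat(rows, ignore_index=True)
    )


@dataclass
class AnalysisConfig:
    """Everything one species run needs.

    ``occurrence`` and ``score_sheet`` may be DataFrames or CSV paths.
    ``holdout_n_presence`` overrides ``holdout_fraction`` with an explicit
    presence count for the test set.
    """

    occurrence: pd.DataFrame | str | Path
    score_sheet: pd.DataFrame | str | Path
    species: str = "species"
    learners: tuple[str, ...] = LEARNER_TYPES
    n_bootstraps: int = 500
    vif_threshold: float = 10.0
    holdout_fraction: float = 0.2
    holdout_n_presence: int | None = None
    grids: Mapping[str, dict] | None = None
    cv_folds: int = 10
    maxent_features: tuple[str, ...] = ("linear", "quadratic", "hinge")
    maxent_hinge_knots: int = 5
    n_permutations: int = 5
    pd_top_n: int = 4
    pd_grid_size: int = 50
    seed: int = 0
    out_dir: str | Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "learners" in raw:
            raw["learners"] = tuple(raw["learners"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """All artifacts of one species run."""

    vif_report: VIFReport
    split: DataSplit
    members: list[FittedMember]
    importance: pd.DataFrame
    importance_summary: pd.DataFrame
    scores: pd.Series
    cip: pd.DataFrame
    cip_ranked: pd.DataFrame
    evaluation: EvaluationResult
    pd_curves: list[PartialDependenceCurve]
    manifest: dict = field(default_factory=dict)


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_species_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full pipeline for one species. See module docstring."""
    t0 = time.perf_counter()

    def stage(name: str) -> None:
        log.info("[%s] %-22s %7.2fs", config.species, name, time.perf_counter() - t0)

    table = (
        validate_occurrence(config.occurrence)
        if isinstance(config.occurrence, pd.DataFrame)
        else load_occurrence(config.occurrence)
    )
    sheet = (
        config.score_sheet
        if isinstance(config.score_sheet, pd.DataFrame)
        else climate_mod.load_score_sheet(config.score_sheet)
    )
    root = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(np.random.default_rng(child).integers(2**31))
        for name, child in zip(("holdout", "fit", "importance"), root.spawn(3))
    }

    try:
        vif_report = filter_by_vif(table, threshold=config.vif_threshold)
        screened = table[["id", "presence"] + vif_report.retained]
        stage("vif")

        split = make_holdout(
            screened,
            presence_fraction=config.holdout_fraction,
            seed=seeds["holdout"],
            n_test_presence=config.holdout_n_presence,
        )
        stage("holdout")

        ensemble = HabitatEnsemble(
            learners=config.learners,
            n_bootstraps=config.n_bootstraps,
            grids=config.grids,
            cv_folds=config.cv_folds,
            maxent_features=tuple(config.maxent_features),
            maxent_hinge_knots=config.maxent_hinge_knots,
            random_state=seeds["fit"],
        ).fit(split.train)
        members = ensemble.members_
        samples = {s.bootstrap_id: s for s in ensemble.bootstraps_}
        stage("fit")

        records = importance_records(
            members,
            samples=samples,
            n_permutations=config.n_permutations,
            seed=seeds["importance"],
        )
        summary = aggregate_importance(records)
        stage("importance")

        scores = climate_mod.average_scores(sheet)
        cip = climate_mod.change_importance_product(summary, scores)
        cip_ranked = climate_mod.rank_report(cip)
        stage("cip")

        evaluation = evaluate_members(members, split.test)
        stage("evaluate")

        top = cip_ranked["variable"].head(config.pd_top_n).tolist()
        curves = [
            partial_dependence(members, v, split.train, grid_size=config.pd_grid_size) for v in top
        ]
        stage("partial-dependence")
    except Exception as exc:
        raise RuntimeError(f"{config.species}: pipeline stage failed: {exc}") from exc

    train_ids = set(split.train["id"])
    test_ids = set(split.test["id"])
    bootstrap_ids = set().union(*(set(s.records["id"]) for s in samples.values()))
    manifest = {
        "species": config.species,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_records": int(len(table)),
        "n_presence": int(table["presence"].sum()),
        "n_covariates_input": len(covariate_columns(table)),
        "n_covariates_retained": len(vif_report.retained),
        "n_removed_by_vif": len(vif_report.removed),
        "n_test_records": int(len(split.test)),
        "n_test_presence": int(split.test["presence"].sum()),
        "n_train_presence": int(split.train["presence"].sum()),
        "n_bootstraps": config.n_bootstraps,
        "bootstrap_size": int(len(next(iter(samples.values())).records)) if samples else 0,
        "n_learners": len(config.learners),
        "n_members": len(members),
        "test_train_id_overlap": int(len(train_ids & test_ids)),
        "test_bootstrap_id_overlap": int(len(test_ids & bootstrap_ids)),
        "digests": {
            "importance": _digest(records),
            "importance_summary": _digest(summary),
            "cip": _digest(cip),
            "evaluation": _digest(evaluation.per_member),
        },
    }
    bundle = ReportBundle(
        vif_report=vif_report,
        split=split,
        members=members,
        importance=records,
        importance_summary=summary,
        scores=scores,
        cip=cip,
        cip_ranked=cip_ranked,
        evaluation=evaluation,
        pd_curves=curves,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.vif_report.to_frame().to_csv(out / "vif.csv", index=False)
    bundle.split.membership().to_csv(out / "split.csv", index=False)
    bundle.importance.to_csv(out / "importance.csv", index=False)
    bundle.importance_summary.to_csv(out / "importance_summary.csv", index=False)
    bundle.cip.to_csv(out / "cip.csv", index=False)
    bundle.cip_ranked.to_csv(out / "cip_ranked.csv", index=False)
    bundle.evaluation.per_member.to_csv(out / "evaluation_members.csv", index=False)
    bundle.evaluation.summary.to_csv(out / "evaluation_summary.csv", index=False)
    if bundle.pd_curves:
        pd.concat([c.to_frame() for c in bundle.pd_curves], ignore_index=True).to_csv(
            out / "partial_dependence.csv", index=False
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)


def plot_partial_dependence(curves: Sequence[PartialDependenceCurve], path: str | Path | None = None):
    """Small-multiples plot of ensemble partial dependence with +/- SD bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(curves)
    ncols = min(n, 2)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 3.2 * nrows), squeeze=False)
    for ax, c in zip(axes.ravel(), curves):
        ax.plot(c.grid, c.mean, color="tab:blue")
        ax.fill_between(c.grid, c.mean - c.sd, c.mean + c.sd, alpha=0.25, color="tab:blue")
        ax.set_xlabel(c.variable)
        ax.set_ylabel("P(presence)")
        ax.set_ylim(-0.02, 1.02)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
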