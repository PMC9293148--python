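"""Synthetic presence-absence data with known structure.

The habitat analysis downstream assumes a very particular kind of input:
severely unbalanced presence/absence records (a few hundred seal presences
against thousands of background absences), continuous environmental
covariates that are mutually correlated -- some of them collinear enough to
trip a variance-inflation screen -- and a small set of covariates that
actually drive the probability of presence. This module manufactures
datasets with exactly that structure, together with the generating truth,
so every downstream stage (collinearity screening, balanced bootstrapping,
ensemble fitting, importance ranking) can be validated against a known
answer.

Covariates are drawn from a multivariate normal with a user-specified
correlation matrix; "distance-to-feature" style covariates, which in real
data are positive and right-skewed, are obtained by exponentiating a
Gaussian column. Near-duplicate covariates (e.g. two ice metrics derived
from the same sensor) are manufactured by copying a column and adding
Gaussian noise. Presence labels follow a Bernoulli-logistic model on the
latent Gaussian covariates, conditioned on exact class totals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_covariates",
    "generate_occurrence",
    "generate_score_sheet",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic presence-absence dataset.

    Parameters
    ----------
    n_presence, n_absence:
        Exact class totals of the returned table. Real surveys of this kind
        have presences << absences; the ratio is a free parameter here.
    covariate_names:
        Names of the base covariates (before collinear copies are added).
    correlation:
        Correlation matrix of the base covariates (defaults to identity).
        Must be symmetric positive semi-definite with unit diagonal.
    driver_coefficients:
        Mapping covariate name -> logistic-scale coefficient. Names absent
        from the mapping get coefficient 0; the nonzero entries define the
        "true driver" set recorded in the output truth.
    intercept:
        Logistic-scale intercept; controls the marginal presence rate of
        the generating process (before conditioning on exact counts).
    collinear_pairs:
        Sequence of ``(source, copy, noise_sd)`` triples. Each appends a
        new column ``copy = source + Normal(0, noise_sd)``, giving
        controlled near-collinearity (``noise_sd = 0`` is an exact copy).
    skewed_covariates:
        Base covariates to exponentiate after the Gaussian draw, producing
        positive right-skewed columns akin to distances. Coefficients act
        on the latent Gaussian, so the presence-probability link remains
        monotone in the stored covariate.
    seed:
        Root seed; per-stage generators are spawned from it so covariate
        generation, labelling and score sheets are independently
        reproducible.
    """

    n_presence: int
    n_absence: int
    covariate_names: tuple[str, ...]
    correlation: np.ndarray | None = None
    driver_coefficients: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    collinear_pairs: tuple[tuple[str, str, float], ...] = ()
    skewed_covariates: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_presence < 1:
            raise ValueError("n_presence must be >= 1")
        if self.n_absence < 0:
            raise ValueError("n_absence must be >= 0")
        names = tuple(self.covariate_names)
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        object.__setattr__(self, "covariate_names", names)
        object.__setattr__(self, "collinear_pairs", tuple(tuple(p) for p in self.collinear_pairs))
        object.__setattr__(self, "skewed_covariates", tuple(self.skewed_covariates))
        corr = self.correlation
        if corr is not None:
            corr = np.asarray(corr, dtype=float)
            p = len(names)
            if corr.shape != (p, p):
                raise ValueError(f"correlation must be {p}x{p}, got {corr.shape}")
            if not np.allclose(corr, corr.T, atol=1e-12):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
                raise ValueError("correlation matrix must have unit diagonal")
            eigmin = float(np.linalg.eigvalsh(corr).min())
            if eigmin < -1e-10:
                raise ValueError(
                    "correlation matrix is not positive semi-definite "
                    f"(smallest eigenvalue {eigmin:.3e})"
                )
            object.__setattr__(self, "correlation", corr)
        for source, copy, noise_sd in self.collinear_pairs:
            if source not in names:
                raise ValueError(f"collinear source {source!r} is not a declared covariate")
            if copy in names:
                raise ValueError(f"collinear copy {copy!r} clashes with a declared covariate")
            if noise_sd < 0:
                raise ValueError("collinear noise_sd must be >= 0")
        for name in self.driver_coefficients:
            if name not in names:
                raise ValueError(f"driver coefficient for unknown covariate {name!r}")
        for name in self.skewed_covariates:
            if name not in names:
                raise ValueError(f"skewed covariate {name!r} is not declared")

    @property
    def all_covariate_names(self) -> tuple[str, ...]:
        return self.covariate_names + tuple(copy for _, copy, _ in self.collinear_pairs)

    @property
    def driver_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.covariate_names if self.driver_coefficients.get(n, 0.0) != 0.0)

    def spawn_rng(self, stage: int) -> np.random.Generator:
        """Child generator for one pipeline stage (0=covariates, 1=labels, 2=scores)."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class SyntheticDataset:
    """An occurrence table plus the truth that generated it."""

    table: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "occurrence.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def _draw_latent(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    p = len(config.covariate_names)
    corr = config.correlation if config.correlation is not None else np.eye(p)
    # Cholesky with a PSD-safe fallback for rank-deficient requests
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, p))
    return z @ chol.T


def _finalize_columns(config: SimulationConfig, latent: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for j, name in enumerate(config.covariate_names):
        col = latent[:, j]
        cols[name] = np.exp(col) if name in config.skewed_covariates else col
    df = pd.DataFrame(cols)
    for source, copy, noise_sd in config.collinear_pairs:
        noise = rng.normal(0.0, noise_sd, size=len(df)) if noise_sd > 0 else 0.0
        df[copy] = df[source].to_numpy() + noise
    return df


def generate_covariates(config: SimulationConfig, n: int | None = None) -> pd.DataFrame:
    """Draw the covariate pool: correlated Gaussians plus manufactured copies.

    Returns a DataFrame with one row per record and one column per covariate
    (declared covariates first, collinear copies appended). A hidden
    ``_latent_eta`` column carries the linear predictor on the latent
    Gaussian scale for use by :func:`generate_occurrence`; it is dropped
    from the final occurrence table.
    """
    if n is None:
        n = config.n_presence + config.n_absence
    rng = config.spawn_rng(0)
    latent = _draw_latent(config, n, rng)
    df = _finalize_columns(config, latent, rng)
    beta = np.array([config.driver_coefficients.get(name, 0.0) for name in config.covariate_names])
    df["_latent_eta"] = config.intercept + latent @ beta
    return df


_MAX_LABEL_PASSES = 200


def generate_occurrence(covariates: pd.DataFrame, config: SimulationConfig) -> SyntheticDataset:
    """Label covariate rows Bernoulli-logistic, conditioned on exact class totals.

    Rows are labelled presence with probability ``logistic(eta)`` and
    accepted into the presence or absence bucket until both buckets hit the
    configured totals; extra passes re-sample rows (with replacement) from
    the pool and re-draw their labels, so the result is a draw from the
    generating model conditioned on the exact counts. If the probabilities
    are so degenerate that a class cannot be filled by rejection, remaining
    rows are force-relabelled (highest probability first) with a warning.
    """
    if "_latent_eta" not in covariates.columns:
        raise ValueError("covariates must come from generate_covariates (missing linear predictor)")
    rng = config.spawn_rng(1)
    eta = covariates["_latent_eta"].to_numpy()
    prob = 1.0 / (1.0 + np.exp(-eta))
    if prob.mean() < 1e-4 or prob.mean() > 1 - 1e-4:
        warnings.warn(
            "presence probability is nearly degenerate "
            f"(mean {prob.mean():.2e}); labels may need forcing",
            stacklevel=2,
        )

    pool = np.arange(len(covariates))
    pres_idx: list[int] = []
    abs_idx: list[int] = []
    order = rng.permutation(pool)
    for _pass in range(_MAX_LABEL_PASSES):
        labels = rng.random(len(order)) < prob[order]
        for i, is_pres in zip(order, labels):
            if is_pres and len(pres_idx) < config.n_presence:
                pres_idx.append(int(i))
            elif not is_pres and len(abs_idx) < config.n_absence:
                abs_idx.append(int(i))
        if len(pres_idx) == config.n_presence and len(abs_idx) == config.n_absence:
            break
        order = rng.choice(pool, size=len(pool), replace=True)
    else:
        warnings.warn("rejection sampling exhausted; force-relabelling remaining rows", stacklevel=2)
        need_p = config.n_presence - len(pres_idx)
        if need_p > 0:
            extra = pool[np.argsort(-prob)][:need_p]
            pres_idx.extend(int(i) for i in extra)
        need_a = config.n_absence - len(abs_idx)
        if need_a > 0:
            extra = pool[np.argsort(prob)][:need_a]
            abs_idx.extend(int(i) for i in extra)

    idx = np.array(pres_idx + abs_idx)
    presence = np.r_[np.ones(len(pres_idx), dtype=int), np.zeros(len(abs_idx), dtype=int)]
    table = covariates.drop(columns="_latent_eta").iloc[idx].reset_index(drop=True)
    table.insert(0, "presence", presence)
    table.insert(0, "id", [f"rec{k:06d}" for k in range(len(table))])

    truth = {
        "intercept": config.intercept,
        "coefficients": {n: float(config.driver_coefficients.get(n, 0.0)) for n in config.covariate_names},
        "drivers": list(config.driver_names),
        "seed": config.seed,
    }
    return SyntheticDataset(table=table, truth=truth)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Convenience: covariate pool + exact-count occurrence labels in one call."""
    return generate_occurrence(generate_covariates(config), config)


def generate_score_sheet(
    variables: Sequence[str],
    n_raters: int,
    seed: int = 0,
    force_zero: Sequence[str] = (),
    force_three: Sequence[str] = (),
) -> pd.DataFrame:
    """Fixture rater x variable climate-change-score sheet, entries in {0,1,2,3}.

    Each rater scores every variable with an independent uniform draw over
    the four levels (0 = no expected change ... 3 = high expected change).
    ``force_zero`` / ``force_three`` pin designated variables to unanimous
    0 or 3 across raters, which gives oracle tests exact expected means.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    variables = list(variables)
    unknown = (set(force_zero) | set(force_three)) - set(variables)
    if unknown:
        raise ValueError(f"forced variables not in sheet: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    scores = rng.integers(0, 4, size=(n_raters, len(variables)))
    sheet = pd.DataFrame(scores, columns=variables, index=[f"rater{r + 1}" for r in range(n_raters)])
    sheet.index.name = "rater"
    for v in force_zero:
        sheet[v] = 0
    for v in force_three:
        sheet[v] = 3
    return sheet
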