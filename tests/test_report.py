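"""Hold-out metrics, partial dependence and the orchestrated species run."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from icehab.metrics import auc, r_squared
from icehab.models import FittedMember
from icehab.report import (
    AnalysisConfig,
    evaluate_members,
    partial_dependence,
    run_species_analysis,
)
from icehab.simulate import SimulationConfig, generate_score_sheet, simulate_dataset

TINY_GRIDS = {
    "RF": {"max_features": ["sqrt"], "n_estimators": [10]},
    "BRT": {"learning_rate": [0.1], "max_depth": [1], "n_estimators": [10]},
    "MAXENT": {"regularization": [1.0]},
}


class _LogisticStub:
    """Fixed-coefficient model: p = sigmoid(b . x); lets tests control truth."""

    def __init__(self, names, coefs):
        self.names = list(names)
        self.coefs = np.asarray(coefs, dtype=float)

    def predict_proba(self, X):
        p = expit(X[self.names].to_numpy() @ self.coefs)
        return np.column_stack([1 - p, p])


def _stub_member(names, coefs, learner_type="RF", bootstrap_id=0):
    return FittedMember(
        learner_type=learner_type,
        bootstrap_id=bootstrap_id,
        params={},
        cv_score=0.0,
        model=_LogisticStub(names, coefs),
        feature_names=tuple(names),
    )


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_uninformative_scores(self):
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_four_pair_example(self):
        # pairs (0.9,0.6) (0.9,0.1) (0.4,0.6) (0.4,0.1): 3 of 4 concordant
        assert auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_all_pairs_count_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[:2] = [0, 1]
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        pos, neg = s[y == 1], s[y == 0]
        pairs = pos[:, None] - neg[None, :]
        brute = (np.sum(pairs > 0) + 0.5 * np.sum(pairs == 0)) / pairs.size
        assert auc(y, s) == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            auc([1, 1], [0.2, 0.3])


class TestRSquared:
    def test_exact_prediction_gives_one(self):
        assert r_squared([0, 1, 1, 0], [0, 1, 1, 0]) == 1.0

    def test_mean_prediction_gives_zero(self):
        assert r_squared([0.0, 1.0, 1.0, 0.0], [0.5] * 4) == 0.0

    def test_direct_formula_example(self):
        # SS_res = 4*0.0625 = 0.25, SS_tot = 1 -> R^2 = 0.75
        assert r_squared([0, 1, 1, 0], [0.25, 0.75, 0.75, 0.25]) == pytest.approx(0.75)

    def test_zero_variance_rejected_and_corr_variant(self):
        with pytest.raises(ValueError, match="zero variance"):
            r_squared([1.0, 1.0], [0.5, 0.6])
        obs, pred = [0.0, 1.0, 2.0, 3.0], [0.1, 0.9, 2.2, 2.9]
        assert r_squared(obs, pred, variant="corr") == pytest.approx(np.corrcoef(obs, pred)[0, 1] ** 2)


class TestPartialDependence:
    @pytest.fixture(scope="class")
    def data(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {"id": [f"r{i}" for i in range(200)], "presence": rng.integers(0, 2, 200),
             "x0": rng.standard_normal(200), "x1": rng.standard_normal(200)}
        )

    def test_ignored_variable_gives_flat_curve(self, data):
        member = _stub_member(["x0", "x1"], [1.5, 0.0])
        curve = partial_dependence([member], "x1", data, grid_size=12)
        assert np.ptp(curve.mean) < 1e-12

    def test_single_member_has_zero_sd(self, data):
        member = _stub_member(["x0", "x1"], [1.5, 0.0])
        curve = partial_dependence([member], "x0", data, grid_size=12)
        np.testing.assert_allclose(curve.sd, 0.0)

    def test_monotone_generating_shape_recovered(self, data):
        member = _stub_member(["x0", "x1"], [2.0, 0.0])
        curve = partial_dependence([member], "x0", data, grid_size=20)
        assert (np.diff(curve.mean) > 0).all()
        assert curve.grid[0] < curve.grid[-1]
        assert (curve.mean >= 0).all() and (curve.mean <= 1).all()

    def test_sd_pools_across_disagreeing_members(self, data):
        members = [_stub_member(["x0", "x1"], [2.0, 0.0]),
                   _stub_member(["x0", "x1"], [-2.0, 0.0], learner_type="BRT")]
        curve = partial_dependence(members, "x0", data, grid_size=10)
        assert curve.sd.max() > 0.1
        assert set(curve.per_learner["learner_type"]) == {"RF", "BRT"}

    def test_unknown_variable_rejected(self, data):
        with pytest.raises(ValueError, match="not in data"):
            partial_dependence([_stub_member(["x0", "x1"], [1, 0])], "zz", data)


class TestEvaluateMembers:
    def test_metrics_grouped_per_learner(self, small_members, small_split):
        result = evaluate_members(list(small_members.values()), small_split.test)
        assert len(result.per_member) == 3
        assert set(result.summary["learner_type"]) == {"RF", "BRT", "MAXENT"}
        assert result.per_member["auc"].between(0, 1).all()


class TestRunSpeciesAnalysis:
    @pytest.fixture(scope="class")
    def config(self):
        cfg = SimulationConfig(
            n_presence=40,
            n_absence=300,
            covariate_names=("x0", "x1", "x2", "x3"),
            driver_coefficients={"x0": 2.0},
            collinear_pairs=(("x1", "x1_dup", 0.0),),
            intercept=-1.5,
            seed=21,
        )
        ds = simulate_dataset(cfg)
        sheet = generate_score_sheet(
            cfg.all_covariate_names, n_raters=4, seed=21, force_three=["x0"]
        )
        return dict(occurrence=ds.table, score_sheet=sheet)

    @pytest.fixture(scope="class")
    def bundle(self, config):
        return run_species_analysis(
            AnalysisConfig(
                **config,
                n_bootstraps=2,
                grids=TINY_GRIDS,
                maxent_features=("linear",),
                n_permutations=2,
                pd_top_n=2,
                pd_grid_size=8,
                seed=5,
            )
        )

    def test_manifest_counts_consistent(self, bundle):
        m = bundle.manifest
        assert m["n_members"] == m["n_bootstraps"] * m["n_learners"] == 6
        assert m["n_covariates_retained"] == 4  # the exact duplicate is screened out
        assert m["bootstrap_size"] == 2 * m["n_train_presence"]
        assert m["n_test_presence"] * 2 == m["n_test_records"]

    def test_holdout_disjoint_from_all_bootstraps(self, bundle):
        assert bundle.manifest["test_train_id_overlap"] == 0
        assert bundle.manifest["test_bootstrap_id_overlap"] == 0

    def test_outputs_cover_all_members_and_variables(self, bundle):
        retained = set(bundle.vif_report.retained)
        assert set(bundle.importance["variable"]) == retained
        assert len(bundle.evaluation.per_member) == 6
        assert set(bundle.cip_ranked["variable"]) == retained
        assert len(bundle.pd_curves) == 2

    def test_rerun_reproduces_digests(self, config, bundle):
        again = run_species_analysis(
            AnalysisConfig(
                **config,
                n_bootstraps=2,
                grids=TINY_GRIDS,
                maxent_features=("linear",),
                n_permutations=2,
                pd_top_n=2,
                pd_grid_size=8,
                seed=5,
            )
        )
        assert again.manifest["digests"] == bundle.manifest["digests"]

    def test_single_bootstrap_single_learner(self, config):
        bundle = run_species_analysis(
            AnalysisConfig(
                **config,
                learners=("RF",),
                n_bootstraps=1,
                grids=TINY_GRIDS,
                n_permutations=2,
                pd_top_n=1,
                pd_grid_size=5,
                seed=6,
            )
        )
        assert bundle.manifest["n_members"] == 1
        assert (bundle.importance_summary["n_bootstraps"] == 1).all()
        assert (bundle.importance_summary["sd_proportional_importance"] == 0).all()

    def test_artifacts_written_to_disk(self, config, tmp_path_factory):
        out = tmp_path_factory.mktemp("run")
        run_species_analysis(
            AnalysisConfig(
                **config,
                learners=("RF",),
                n_bootstraps=1,
                grids=TINY_GRIDS,
                n_permutations=1,
                pd_top_n=1,
                pd_grid_size=5,
                seed=7,
                out_dir=out,
            )
        )
        for fname in (
            "vif.csv",
            "split.csv",
            "importance.csv",
            "importance_summary.csv",
            "cip.csv",
            "cip_ranked.csv",
            "evaluation_members.csv",
            "evaluation_summary.csv",
            "partial_dependence.csv",
            "manifest.json",
        ):
            assert (out / fname).exists(), fname
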