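"""VIF screening, balanced hold-out and balanced bootstrap sampling."""

import numpy as np
import pandas as pd
import pytest

from icehab.preprocess import (
    VIFFilter,
    compute_vif,
    draw_bootstrap,
    filter_by_vif,
    make_holdout,
)


def _orthonormal_centered(n, k, seed=0):
    """k zero-mean columns, orthonormal in the sample inner product."""
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, k))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    return Q  # columns of Q are combinations of zero-mean columns, hence zero-mean


def _table(cols: dict) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    df.insert(0, "presence", np.tile([0, 1], len(df))[: len(df)])
    df.insert(0, "id", [f"r{i}" for i in range(len(df))])
    return df


class TestComputeVIF:
    def test_orthogonal_covariates_have_unit_vif(self):
        Q = _orthonormal_centered(60, 2)
        vif = compute_vif(_table({"a": Q[:, 0], "b": Q[:, 1]}))
        np.testing.assert_allclose(vif.to_numpy(), 1.0, atol=1e-8)

    def test_exact_linear_dependence_flagged_unbounded(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.standard_normal(50), rng.standard_normal(50)
        vif = compute_vif(_table({"x1": x1, "x2": x2, "x3": x1 + x2}))
        assert np.isinf(vif["x3"])

    def test_closed_form_for_known_sample_correlation(self):
        # x2 = 0.9*x1 + sqrt(1-0.81)*u with exactly orthonormal ingredients,
        # so VIF(x1) = VIF(x2) = 1/(1-0.9^2) and the independent x3 has VIF 1
        Q = _orthonormal_centered(80, 3, seed=2)
        x1 = Q[:, 0]
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * Q[:, 1]
        vif = compute_vif(_table({"x1": x1, "x2": x2, "x3": Q[:, 2]}))
        expected = 1.0 / (1.0 - 0.81)
        np.testing.assert_allclose(vif["x1"], expected, atol=1e-8)
        np.testing.assert_allclose(vif["x2"], expected, atol=1e-8)
        np.testing.assert_allclose(vif["x3"], 1.0, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_ols_oracle_on_random_instances(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        base = rng.standard_normal((60, 6))
        base[:, 3] = base[:, 0] + 0.5 * base[:, 1] + 0.3 * rng.standard_normal(60)
        names = [f"v{j}" for j in range(6)]
        table = _table(dict(zip(names, base.T)))
        vif = compute_vif(table)
        for j, name in enumerate(names):
            others = sm.add_constant(np.delete(base, j, axis=1))
            r2 = sm.OLS(base[:, j], others).fit().rsquared
            np.testing.assert_allclose(vif[name], 1.0 / (1.0 - r2), rtol=1e-8)

    def test_vif_at_least_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5))
        vif = compute_vif(_table({f"c{j}": X[:, j] for j in range(5)}))
        assert (vif >= 1.0 - 1e-12).all()

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_vif(_table({"a": np.ones(30), "b": np.arange(30.0)}))

    def test_too_few_covariates_or_records_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_vif(_table({"a": np.arange(10.0)}))
        with pytest.raises(ValueError, match="records"):
            compute_vif(_table({"a": [1.0, 2.0], "b": [2.0, 1.0], "c": [0.0, 1.0]}))


class TestFilterByVIF:
    def test_uncorrelated_set_fully_retained(self):
        Q = _orthonormal_centered(80, 4, seed=4)
        report = filter_by_vif(_table({f"c{j}": Q[:, j] for j in range(4)}))
        assert report.retained == [f"c{j}" for j in range(4)]
        assert report.removed == []

    def test_exact_duplicate_removed_first(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 4))
        cols = {f"c{j}": X[:, j] for j in range(4)}
        cols["c0_dup"] = X[:, 0].copy()
        report = filter_by_vif(_table(cols))
        assert len(report.retained) == 4
        # alphabetical tie-break between the two unbounded-VIF duplicates
        assert report.removed[0][0] == "c0"
        assert np.isinf(report.removed[0][1])

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 5))
        X[:, 4] = X[:, 0] + X[:, 1] + 0.01 * rng.standard_normal(60)
        table = _table({f"c{j}": X[:, j] for j in range(5)})
        first = filter_by_vif(table)
        again = filter_by_vif(table[["id", "presence"] + first.retained])
        assert again.retained == first.retained
        assert again.removed == []

    def test_default_threshold_is_ten(self):
        import inspect

        assert inspect.signature(filter_by_vif).parameters["threshold"].default == 10.0

    def test_transformer_round_trip(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 3))
        table = _table({"a": X[:, 0], "b": X[:, 1], "b_dup": X[:, 1], "c": X[:, 2]})
        vf = VIFFilter(threshold=10.0).fit(table)
        out = vf.transform(table)
        assert list(out.columns[:2]) == ["id", "presence"]
        assert set(vf.retained_) == set(out.columns) - {"id", "presence"}
        assert len(vf.retained_) == 3
        assert VIFFilter().get_params() == {"threshold": 10.0}


class TestMakeHoldout:
    def test_published_scale_counts(self):
        # 4911 presences at fraction 0.2 -> 982 test presences + 982 absences,
        # leaving 3929 training presences
        rng = np.random.default_rng(8)
        n_p, n_a = 4911, 9000
        table = pd.DataFrame(
            {
                "id": [f"r{i}" for i in range(n_p + n_a)],
                "presence": np.r_[np.ones(n_p, int), np.zeros(n_a, int)],
                "x": rng.standard_normal(n_p + n_a),
                "y": rng.standard_normal(n_p + n_a),
            }
        )
        split = make_holdout(table, presence_fraction=0.2, seed=0)
        assert int(split.test["presence"].sum()) == 982
        assert len(split.test) == 1964
        assert int(split.train["presence"].sum()) == 3929
        assert set(split.train["id"]).isdisjoint(split.test["id"])

    def test_explicit_presence_count_override(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            {
                "id": [f"r{i}" for i in range(172 + 400)],
                "presence": np.r_[np.ones(172, int), np.zeros(400, int)],
                "x": rng.standard_normal(572),
            }
        )
        split = make_holdout(table, seed=1, n_test_presence=38)
        assert len(split.test) == 76
        assert int(split.train["presence"].sum()) == 134

    def test_zero_fraction_degenerates_to_no_test_set(self, small_dataset):
        split = make_holdout(small_dataset.table, presence_fraction=0.0, seed=2)
        assert len(split.test) == 0
        assert len(split.train) == len(small_dataset.table)

    def test_insufficient_absences_rejected(self):
        table = pd.DataFrame(
            {"id": ["a", "b", "c"], "presence": [1, 1, 0], "x": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(ValueError, match="absences"):
            make_holdout(table, seed=0, n_test_presence=2)

    def test_reproducible_given_seed(self, small_dataset):
        a = make_holdout(small_dataset.table, 0.2, seed=5)
        b = make_holdout(small_dataset.table, 0.2, seed=5)
        assert list(a.test["id"]) == list(b.test["id"])


class TestDrawBootstrap:
    def test_balanced_and_contains_every_presence_once(self, small_split):
        bs = draw_bootstrap(small_split.train, bootstrap_id=3, seed=4)
        n_p = int(small_split.train["presence"].sum())
        assert len(bs.records) == 2 * n_p
        assert int(bs.records["presence"].sum()) == n_p
        pres_ids = small_split.train.loc[small_split.train["presence"] == 1, "id"]
        assert sorted(bs.records.loc[bs.records["presence"] == 1, "id"]) == sorted(pres_ids)

    def test_absences_sampled_without_replacement_when_pool_suffices(self, small_split):
        bs = draw_bootstrap(small_split.train, bootstrap_id=0, seed=4)
        absn = bs.records.loc[bs.records["presence"] == 0, "id"]
        assert absn.is_unique

    def test_with_replacement_fallback_when_pool_smaller(self):
        table = pd.DataFrame(
            {
                "id": [f"r{i}" for i in range(8)],
                "presence": [1, 1, 1, 1, 1, 1, 0, 0],
                "x": np.arange(8.0),
            }
        )
        bs = draw_bootstrap(table, bootstrap_id=0, seed=1)
        assert len(bs.records) == 12
        assert int(bs.records["presence"].sum()) == 6

    def test_single_pair_returns_whole_train_set(self):
        table = pd.DataFrame({"id": ["a", "b"], "presence": [1, 0], "x": [0.0, 1.0]})
        bs = draw_bootstrap(table, bootstrap_id=0, seed=0)
        assert sorted(bs.records["id"]) == ["a", "b"]

    def test_same_seed_same_selection(self, small_split):
        a = draw_bootstrap(small_split.train, 7, seed=9)
        b = draw_bootstrap(small_split.train, 7, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_empty_class_rejected(self):
        table = pd.DataFrame({"id": ["a", "b"], "presence": [1, 1], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="presence and one absence"):
            draw_bootstrap(table, 0, seed=0)
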