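"""Standardized fits, R-squared identities, LOO, subset search, scaling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voidshape import (
    best_subset,
    fit_chemistry_to_void,
    fit_linear,
    generate_regression_fixture,
    leave_k_out_ratio,
    loo_cv,
    r_squared,
    standardize,
)
from voidshape.regression import (
    DegenerateColumnError,
    RankDeficiencyError,
    coefficients_table,
)


class TestStandardize:
    def test_three_point_column_population_sd(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, scale = standardize(df)
        np.testing.assert_allclose(out["x"], [-1.224744871, 0, 1.224744871],
                                   atol=1e-9)
        assert scale.sd["x"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std()
        out, _ = standardize(pd.DataFrame({"x": x}))
        np.testing.assert_allclose(out["x"], x, atol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(DegenerateColumnError, match="flat"):
            standardize(df)

    def test_inverse_round_trips(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(3, 2, 30),
                           "b": rng.uniform(0, 9, 30)})
        out, scale = standardize(df)
        np.testing.assert_allclose(scale.inverse(out), df, atol=1e-12)


class TestFitLinear:
    def test_exact_linear_data_r2_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 3))
        w_true = np.array([0.4, -1.1, 0.7])
        w, r2 = fit_linear(X, X @ w_true)
        np.testing.assert_allclose(w, w_true, atol=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_single_feature_weight_is_pearson_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(scale=0.5, size=40)
        xs = (x - x.mean()) / x.std()
        ys = (y - y.mean()) / y.std()
        w, _ = fit_linear(xs[:, None], ys)
        assert w[0] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_orthogonal_target_gives_null_weights(self):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        w, r2 = fit_linear(X, y)
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(RankDeficiencyError):
            fit_linear(X, rng.normal(size=20), feature_names=["a", "b"])


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, np.full(3, y.mean())) == 0.0

    def test_hand_computed_case(self):
        # SS_res = 0.01 + 0.01 + 0 = 0.02; SS_tot = 2 -> R^2 = 0.99
        r2 = r_squared([1.0, 2.0, 3.0], [1.1, 1.9, 3.0])
        assert r2 == pytest.approx(0.99, abs=1e-12)

    def test_bad_predictor_goes_negative(self):
        assert r_squared([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) < 0

    def test_constant_actuals_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_identities_hold_for_random_data(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=10)
        if np.ptp(y) == 0:
            return
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full_like(y, y.mean())) == 0.0


class TestLooCv:
    def test_exact_line_perfect_loo(self):
        x = np.arange(10.0)[:, None]
        y = 2.0 * np.arange(10.0) + 1.0
        mse, r2l, preds = loo_cv(x, y)
        assert mse == pytest.approx(0.0, abs=1e-18)
        assert r2l == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(preds, y, atol=1e-9)

    def test_matches_hand_executed_four_folds(self):
        # independent fold-by-fold execution with closed-form simple
        # regression on each 3-point training set
        x = np.array([0.0, 1.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 2.5, 5.0])
        expected = np.empty(4)
        for k in range(4):
            tr = [i for i in range(4) if i != k]
            xt, yt = x[tr], y[tr]
            xm, xs = xt.mean(), xt.std()
            ym, ys = yt.mean(), yt.std()
            # on standardized data the slope is the Pearson correlation
            r = np.mean((xt - xm) / xs * (yt - ym) / ys)
            expected[k] = ym + ys * r * (x[k] - xm) / xs
        mse, r2l, preds = loo_cv(x[:, None], y)
        np.testing.assert_allclose(preds, expected, atol=1e-10)
        assert mse == pytest.approx(np.mean((y - expected) ** 2), abs=1e-10)

    def test_loo_never_beats_training_fit_on_fixtures(self):
        worse = 0
        for seed in range(10):
            fix = generate_regression_fixture(20, [0.8, -0.6, 0.3], 0.3,
                                              seed=seed)
            _, r2 = fit_linear(*_std(fix.X, fix.y))
            _, r2l, _ = loo_cv(fix.X, fix.y)
            if r2l <= r2 + 1e-12:
                worse += 1
        assert worse == 10  # empirical regularity, checked not proven

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            loo_cv(np.ones((4, 2)), np.arange(4.0))


def _std(X, y):
    Xs = (X - X.mean(0)) / X.std(0)
    ys = (y - y.mean()) / y.std()
    return Xs, ys


class TestBestSubset:
    def _table(self, seed=0, n=20, noise=0.05):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n, 4)),
                          columns=["V", "S", "L", "nbr"])
        df["y"] = 0.8 * df["V"] - 0.6 * df["S"] + rng.normal(
            scale=noise, size=n)
        return df

    def test_recovers_true_feature_pair(self):
        df = self._table(seed=5)
        res = best_subset(df, ["V", "S", "L", "nbr"], "y")
        assert set(res.features) == {"V", "S"}
        assert res.r2 > 0.98

    def test_single_candidate_selected(self):
        df = self._table(seed=6)
        res = best_subset(df, ["V"], "y")
        assert res.features == ["V"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_exhaustive_enumeration(self, seed):
        # oracle: enumerate all 2^p - 1 subsets with raw numpy only
        rng = np.random.default_rng(100 + seed)
        p = 5
        feats = [f"f{j}" for j in range(p)]
        df = pd.DataFrame(rng.normal(size=(16, p)), columns=feats)
        w = rng.normal(size=p) * (rng.random(p) > 0.4)
        df["y"] = df[feats].to_numpy() @ w + rng.normal(scale=0.2, size=16)

        y = df["y"].to_numpy()
        best_mse, best_combo = np.inf, None
        for size in range(1, p + 1):
            for combo in itertools.combinations(sorted(feats), size):
                X = df[list(combo)].to_numpy()
                n = len(y)
                preds = np.empty(n)
                ok = True
                for k in range(n):
                    tr = np.arange(n) != k
                    Xt, yt = X[tr], y[tr]
                    xm, xs = Xt.mean(0), Xt.std(0)
                    ym, ys = yt.mean(), yt.std()
                    if np.any(xs <= 0) or ys <= 0:
                        ok = False
                        break
                    ww, *_ = np.linalg.lstsq((Xt - xm) / xs, (yt - ym) / ys,
                                             rcond=None)
                    preds[k] = ym + ys * (((X[k] - xm) / xs) @ ww)
                if not ok:
                    continue
                mse = np.mean((y - preds) ** 2)
                if mse < best_mse - 1e-15:
                    best_mse, best_combo = mse, combo
        res = best_subset(df, feats, "y")
        assert tuple(res.features) == best_combo
        assert res.mse_loo == pytest.approx(best_mse, rel=1e-10)

    def test_r2_criterion_warns_and_picks_full_set(self):
        df = self._table(seed=7)
        with pytest.warns(UserWarning, match="full feature set"):
            res = best_subset(df, ["V", "S", "L", "nbr"], "y",
                              criterion="r2")
        assert set(res.features) == {"V", "S", "L", "nbr"}

    def test_adding_features_never_lowers_r2(self):
        df = self._table(seed=8, noise=0.5)
        feats = ["V", "S", "L", "nbr"]
        r2_prev = -np.inf
        for size in range(1, 5):
            best_r2 = max(
                fit_linear(*_std(df[list(c)].to_numpy(),
                                 df["y"].to_numpy()))[1]
                for c in itertools.combinations(feats, size))
            assert best_r2 >= r2_prev - 1e-12
            r2_prev = best_r2

    def test_scale_equivariance(self):
        df = self._table(seed=9)
        res1 = best_subset(df, ["V", "S", "L", "nbr"], "y")
        df2 = df.copy()
        df2["V"] = df2["V"] * 37.5  # positive rescale of a raw column
        res2 = best_subset(df2, ["V", "S", "L", "nbr"], "y")
        assert res1.features == res2.features
        np.testing.assert_allclose(res1.weights, res2.weights, atol=1e-10)
        assert res1.mse_loo == pytest.approx(res2.mse_loo, abs=1e-10)
        assert res1.r2 == pytest.approx(res2.r2, abs=1e-10)


class TestLeaveKOut:
    def test_k1_ratio_is_exactly_one(self):
        fix = generate_regression_fixture(20, [0.7, -0.5], 0.1, seed=0)
        out = leave_k_out_ratio(fix.X, fix.y, k=1)
        assert out == {1: 1.0}

    def test_noiseless_data_guarded(self):
        fix = generate_regression_fixture(20, [1.0], 0.0, seed=1)
        out = leave_k_out_ratio(fix.X, fix.y, k=3)
        assert out[2] == 1.0 and out[3] == 1.0

    def test_ratio_near_one_for_well_specified_model(self):
        # error should grow like 1/sqrt(N): the rescaled ratio stays near 1
        ratios2, ratios3 = [], []
        for seed in range(50):
            fix = generate_regression_fixture(20, [0.7, -0.5], 0.1,
                                              seed=seed)
            out = leave_k_out_ratio(fix.X, fix.y, k=3, n_repeats=200,
                                    seed=seed)
            ratios2.append(out[2])
            ratios3.append(out[3])
        assert 0.7 < np.mean(ratios2) < 1.4
        assert 0.7 < np.mean(ratios3) < 1.4

    def test_insufficient_rows_rejected(self):
        fix = generate_regression_fixture(8, [1.0, 2.0, 0.5, 1.5], 0.1,
                                          seed=2)
        with pytest.raises(ValueError):
            leave_k_out_ratio(fix.X, fix.y, k=3)


class TestChemistryToVoid:
    def _tables(self, seed=0, n=20, p_chem=4, targets=("V", "S", "L")):
        rng = np.random.default_rng(seed)
        names = [f"aa{i}" for i in range(n)]
        chem = pd.DataFrame(rng.normal(size=(n, p_chem)),
                            columns=[f"c{j}" for j in range(p_chem)],
                            index=names)
        void = pd.DataFrame(index=names)
        self.true = {}
        for t in targets:
            w = rng.normal(size=p_chem) * (rng.random(p_chem) > 0.5)
            if not np.any(w):
                w[0] = 1.0
            void[t] = chem.to_numpy() @ w + rng.normal(scale=0.05, size=n)
            self.true[t] = w
        return chem, void

    def test_one_result_per_void_variable(self):
        chem, void = self._tables(seed=3)
        res = fit_chemistry_to_void(chem, void,
                                    chem_features=list(chem.columns),
                                    void_columns=list(void.columns))
        assert set(res) == set(void.columns)
        for t, r in res.items():
            assert r.target == t and len(r.features) >= 1

    def test_linear_map_recovered_with_high_r2(self):
        chem, void = self._tables(seed=4)
        res = fit_chemistry_to_void(chem, void,
                                    chem_features=list(chem.columns),
                                    void_columns=list(void.columns))
        for t, r in res.items():
            assert r.r2 > 0.9

    def test_row_mismatch_rejected(self):
        chem, void = self._tables(seed=5)
        with pytest.raises(ValueError, match="aa0"):
            fit_chemistry_to_void(chem.drop(index="aa0"), void)

    def test_null_targets_show_no_spurious_confidence(self):
        # a void variable independent of all chemistry should not look
        # predictable out of sample
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            names = [f"aa{i}" for i in range(20)]
            chem = pd.DataFrame(rng.normal(size=(20, 4)),
                                columns=list("abcd"), index=names)
            void = pd.DataFrame({"V": rng.normal(size=20)}, index=names)
            res = fit_chemistry_to_void(chem, void,
                                        chem_features=list("abcd"),
                                        void_columns=["V"])
            vals.append(res["V"].r2_loo)
        assert np.mean(vals) <= 0.2
        assert np.median(vals) <= 0.0

    def test_coefficients_table_layout(self):
        chem, void = self._tables(seed=6)
        res = fit_chemistry_to_void(chem, void,
                                    chem_features=list(chem.columns),
                                    void_columns=list(void.columns))
        tab = coefficients_table(res)
        assert set(tab.index) == set(void.columns)
        assert {"r2", "r2_loo"} <= set(tab.columns)
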