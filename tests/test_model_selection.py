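"""Model development, filtering, validation and nulls vs independent oracles."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import actidep as a
from actidep.model_selection import FittedModel

import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor


def _table(n=12, k=3, seed=0, beta=None, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, k))
    names = [f"x{i}" for i in range(k)]
    beta = np.zeros(k) if beta is None else np.asarray(beta, float)
    y = 20 + X @ beta + rng.normal(0, noise, n)
    df = pd.DataFrame(X, columns=names)
    df["MADRS"] = y
    return df


class TestFitOls:
    def test_exact_linear_fit(self):
        df = _table(12, 1, seed=1, beta=[3.0], noise=0.0)
        m = a.fit_ols(df, ("x0",))
        assert m.r_squared == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_noise_r2_near_zero(self):
        df = _table(4000, 1, seed=2, beta=[0.0], noise=1.0)
        assert a.fit_ols(df, ("x0",)).r_squared < 0.01

    def test_matches_statsmodels_oracle(self):
        df = _table(12, 3, seed=3, beta=[1.0, -2.0, 0.5], noise=0.5)
        m = a.fit_ols(df, ("x0", "x1", "x2"))
        X = sm.add_constant(df[["x0", "x1", "x2"]])
        fit = sm.OLS(df["MADRS"], X).fit()
        assert m.intercept == pytest.approx(fit.params["const"], abs=1e-8)
        np.testing.assert_allclose(m.coefficients,
                                   fit.params[["x0", "x1", "x2"]], atol=1e-8)
        assert m.r_squared == pytest.approx(fit.rsquared, abs=1e-10)

    def test_matches_pseudoinverse_oracle(self):
        df = _table(12, 3, seed=4, beta=[2.0, 0.0, -1.0], noise=1.0)
        m = a.fit_ols(df, ("x0", "x1", "x2"))
        A = np.column_stack([np.ones(12), df[["x0", "x1", "x2"]].to_numpy()])
        beta = np.linalg.pinv(A) @ df["MADRS"].to_numpy()
        np.testing.assert_allclose(np.r_[m.intercept, m.coefficients],
                                   beta, atol=1e-8)

    def test_standardized_coefficients_affine_invariant(self):
        df = _table(20, 2, seed=5, beta=[1.5, -0.5], noise=1.0)
        m1 = a.fit_ols(df, ("x0", "x1"))
        df2 = df.copy()
        df2["x0"] = df2["x0"] * 100 - 7
        m2 = a.fit_ols(df2, ("x0", "x1"))
        np.testing.assert_allclose(m1.standardized_coefficients,
                                   m2.standardized_coefficients, atol=1e-10)

    def test_rank_deficiency_raises(self):
        df = _table(12, 2, seed=6)
        df["x1"] = 2 * df["x0"]
        with pytest.raises(a.SingularDesignError):
            a.fit_ols(df, ("x0", "x1"))


class TestVif:
    def test_orthogonal_predictors_unity(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame({"x0": np.cos(2 * np.pi * t / n),
                           "x1": np.sin(2 * np.pi * t / n)})
        df["MADRS"] = 20.0 + df["x0"]
        np.testing.assert_allclose(a.vif(df, ("x0", "x1")), 1.0, atol=1e-10)

    def test_correlation_09_closed_form(self):
        # construct exact sample correlation 0.9 via Gram-Schmidt
        rng = np.random.default_rng(7)
        u = rng.normal(0, 1, 40)
        u = (u - u.mean()) / u.std()
        v = rng.normal(0, 1, 40)
        v = v - v.mean() - u * (u @ (v - v.mean())) / (u @ u)
        v /= v.std()
        df = pd.DataFrame({"x0": u, "x1": 0.9 * u + np.sqrt(1 - 0.81) * v})
        df["MADRS"] = 0.0
        np.testing.assert_allclose(a.vif(df, ("x0", "x1")),
                                   1 / (1 - 0.81), rtol=1e-9)

    def test_duplicated_predictor_infinite(self):
        df = _table(12, 1, seed=8)
        df["x1"] = df["x0"]
        assert np.isinf(a.vif(df, ("x0", "x1"))).all()

    def test_single_predictor_is_one(self):
        df = _table(12, 1, seed=9)
        np.testing.assert_array_equal(a.vif(df, ("x0",)), [1.0])

    def test_matches_statsmodels_oracle(self):
        df = _table(30, 4, seed=10, beta=[1, 1, 1, 1], noise=1.0)
        df["x3"] = df["x0"] * 0.8 + df["x3"] * 0.2
        preds = ["x0", "x1", "x2", "x3"]
        got = a.vif(df, preds)
        X = sm.add_constant(df[preds]).to_numpy()
        expected = [variance_inflation_factor(X, j + 1) for j in range(4)]
        np.testing.assert_allclose(got, expected, rtol=1e-8)


class TestEnumerateModels:
    def test_full_space_count(self):
        assert sum(1 for _ in a.enumerate_models(a.MODEL_FEATURES, 6)) == 14892

    @pytest.mark.parametrize("n_feat,max_size,expected", [
        (3, 2, 6), (4, 4, 15), (10, 10, 1023)])
    def test_powerset_identity(self, n_feat, max_size, expected):
        names = [f"f{i}" for i in range(n_feat)]
        specs = list(a.enumerate_models(names, max_size))
        assert len(specs) == expected
        assert len(set(specs)) == expected  # uniqueness
        oracle = set(chain.from_iterable(
            combinations(names, k) for k in range(1, max_size + 1)))
        assert set(specs) == oracle

    def test_max_size_exceeds_features(self):
        with pytest.raises(ValueError):
            list(a.enumerate_models(["a", "b"], 3))

    def test_deterministic_order(self):
        assert (list(a.enumerate_models(["a", "b", "c"], 2))
                == [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c")])


def _stub(predictors, vif=1.2, r2=0.67, rmse=1.84):
    k = len(predictors)
    return FittedModel(predictors=tuple(predictors), intercept=0.0,
                       coefficients=np.zeros(k),
                       standardized_coefficients=np.zeros(k),
                       r_squared=r2, rmse=rmse,
                       vif=np.full(k, float(vif)))


class TestInternalFilter:
    def test_typical_survivor_passes(self):
        assert a.internal_filter(_stub(("a", "b"), vif=1.2, r2=0.67, rmse=1.84))

    @pytest.mark.parametrize("kw", [
        dict(r2=0.5), dict(vif=5.0), dict(rmse=3.0),
        dict(r2=0.49), dict(vif=7.0), dict(rmse=3.5),
    ])
    def test_boundaries_are_strict(self, kw):
        assert not a.internal_filter(_stub(("a",), **{
            "vif": kw.get("vif", 1.0), "r2": kw.get("r2", 0.9),
            "rmse": kw.get("rmse", 1.0)}))

    def test_twenty_model_fixture_straddling_thresholds(self):
        rng = np.random.default_rng(17)
        models, expected = [], []
        for _ in range(20):
            v = rng.choice([1.0, 4.9, 5.0, 6.0])
            r2 = rng.choice([0.4, 0.5, 0.51, 0.9])
            rmse = rng.choice([1.0, 2.99, 3.0, 4.0])
            models.append(_stub(("a", "b"), vif=v, r2=r2, rmse=rmse))
            expected.append(v < 5 and r2 > 0.5 and rmse < 3)
        got = [a.internal_filter(m) for m in models]
        assert got == expected

    def test_survivors_satisfy_all_inequalities(self, brute_results):
        survivors, _ = brute_results
        for m in survivors[::50]:
            assert np.all(m.vif < 5) and m.r_squared > 0.5 and m.rmse < 3


class TestStepwise:
    def test_true_predictor_enters_first(self):
        df = _table(40, 10, seed=11, beta=[2.0] + [0.0] * 9, noise=0.3)
        path = a.stepwise_select(df, criterion="F",
                                 feature_names=[f"x{i}" for i in range(10)])
        assert path and path[0].predictors == ("x0",)

    def test_pure_noise_selects_nothing(self):
        df = _table(40, 5, seed=12, noise=1.0)
        path = a.stepwise_select(df, criterion="F", alpha_enter=1e-6,
                                 feature_names=[f"x{i}" for i in range(5)])
        assert path == []

    def test_max_size_honored(self):
        df = _table(60, 10, seed=13, beta=np.linspace(3, 1, 10), noise=0.01)
        path = a.stepwise_select(df, criterion="AIC",
                                 feature_names=[f"x{i}" for i in range(10)],
                                 max_size=6)
        assert max(m.size for m in path) <= 6

    def test_excluded_features_never_selected(self, cohort_pair):
        train, _ = cohort_pair
        path = a.stepwise_select(train, criterion="F",
                                 excluded=("age", "period"))
        for m in path:
            assert "age" not in m.predictors and "period" not in m.predictors

    def test_greedy_never_beats_best_subset(self, cohort_pair, brute_results):
        train, _ = cohort_pair
        for criterion in ("F", "AIC"):
            path = a.stepwise_select(train, criterion=criterion)
            if not path:
                continue
            final = path[-1]
            best_rmse = min(
                (a.fit_ols(train, spec).rmse
                 for spec in a.enumerate_models(a.MODEL_FEATURES, final.size)
                 if len(spec) == final.size), default=np.inf)
            assert final.rmse >= best_rmse - 1e-9


class TestExternalValidation:
    def test_perfect_model_passes(self):
        df = _table(12, 1, seed=14, beta=[2.0], noise=0.0)
        m = a.fit_ols(df, ("x0",))
        r = a.external_validate(m, df)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.rmse == pytest.approx(0.0, abs=1e-9)
        assert r.passed_external

    def test_constant_prediction_fails_flagged(self):
        df = _table(12, 1, seed=15, beta=[1.0], noise=0.5)
        m = _stub(("x0",), r2=0.9, rmse=1.0)  # zero coefficients
        r = a.external_validate(m, df)
        assert r.undefined_r and not r.passed_external

    def test_matches_direct_formula_oracle(self):
        df = _table(12, 2, seed=16, beta=[1.0, -1.0], noise=1.0)
        m = a.fit_ols(df, ("x0", "x1"))
        other = _table(12, 2, seed=17, beta=[1.0, -1.0], noise=1.0)
        r = a.external_validate(m, other)
        pred = (m.intercept + other[["x0", "x1"]].to_numpy() @ m.coefficients)
        y = other["MADRS"].to_numpy()
        r_oracle = (np.mean((pred - pred.mean()) * (y - y.mean()))
                    / (pred.std() * y.std()))
        rmse_oracle = np.sqrt(np.mean((pred - y) ** 2))
        assert r.pearson_r == pytest.approx(r_oracle, abs=1e-10)
        assert r.rmse == pytest.approx(rmse_oracle, abs=1e-10)


class TestCriticalR:
    def test_n12_alpha05(self):
        assert a.critical_pearson_r(12) == pytest.approx(0.576, abs=5e-4)

    def test_n5(self):
        assert a.critical_pearson_r(5) == pytest.approx(0.878, abs=5e-4)

    def test_alpha_to_one_limit(self):
        assert a.critical_pearson_r(12, alpha=0.9999) < 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            a.critical_pearson_r(2)


class TestNulls:
    def test_dummy_rmse_examples(self):
        assert a.dummy_rmse([29, 29, 29]) == 0.0
        assert a.dummy_rmse([27, 31]) == pytest.approx(2.0)
        rng = np.random.default_rng(18)
        y = rng.integers(18, 41, 12)
        assert a.dummy_rmse(y) == pytest.approx(np.sqrt(
            np.mean((y - y.mean()) ** 2)))

    def test_collapsed_range(self):
        null = a.random_null([20, 25, 30], n_sim=100, value_range=(25, 25),
                             seed=0)
        expected = np.sqrt(np.mean((np.array([20, 25, 30]) - 25.0) ** 2))
        np.testing.assert_allclose(null.rmse_samples, expected)

    def test_deterministic_given_seed(self):
        y = [20, 25, 30, 35]
        n1 = a.random_null(y, n_sim=1000, seed=9)
        n2 = a.random_null(y, n_sim=1000, seed=9)
        np.testing.assert_array_equal(n1.rmse_samples, n2.rmse_samples)

    def test_quantile_convergence(self):
        y = np.random.default_rng(19).integers(18, 41, 12)
        small = a.random_null(y, n_sim=10_000, seed=1)
        big = a.random_null(y, n_sim=200_000, seed=2)
        for x in np.linspace(4, 12, 9):
            assert abs(small.prob_at_most(x) - big.prob_at_most(x)) < 0.01


class TestReporting:
    def test_occurrence_single_size(self):
        models = [_stub((f,)) for f in ("a", "b", "c")]
        t = a.predictor_occurrence(models, ("a", "b", "c"))
        np.testing.assert_allclose(t[1], 1 / 3)

    def test_occurrence_combinatorial_oracle(self):
        names = [f"f{i}" for i in range(16)]
        models = [_stub(spec) for spec in a.enumerate_models(names, 2)]
        t = a.predictor_occurrence(models, names)
        np.testing.assert_allclose(t[1], 1 / 16)
        np.testing.assert_allclose(t[2], 2 / 16)
        np.testing.assert_allclose(t["average"], (1 / 16 + 2 / 16) / 2)

    def test_absent_feature_zero(self):
        t = a.predictor_occurrence([_stub(("a",))], ("a", "b"))
        assert t.loc["b", "average"] == 0.0

    def test_residual_profile_counting(self):
        df = pd.DataFrame({"x": [0.0, 0.0, 0.0],
                           "MADRS": [0.5, 1.5, 2.5]})
        m = FittedModel(("x",), 0.0, np.array([1.0]), np.array([0.0]),
                        0.0, 0.0, np.array([1.0]))
        prof = a.residual_profile([m], df)
        np.testing.assert_allclose(prof.loc[0],
                                   [1 / 3, 2 / 3, 1.0, 1.0, 1.0])
        assert (np.diff(prof.loc["average"]) >= 0).all()

    def test_bland_altman(self):
        assert a.bland_altman([1, 2, 3], [1, 2, 3]) == {
            "mean_diff": 0.0, "loa_low": 0.0, "loa_high": 0.0}
        r = a.bland_altman([5, 6, 7], [2, 3, 4])
        assert r == {"mean_diff": 3.0, "loa_low": 3.0, "loa_high": 3.0}
        rng = np.random.default_rng(20)
        obs, pred = rng.normal(30, 3, 12), rng.normal(30, 3, 12)
        r = a.bland_altman(obs, pred)
        d = obs - pred
        assert r["mean_diff"] == pytest.approx(d.mean())
        assert r["loa_high"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            a.bland_altman([1, 2], [1, 2, 3])


class TestCohortCompare:
    def test_identical_tables_p_one(self):
        df = _table(12, 2, seed=21)
        df["sex"] = [0, 1] * 6
        out = a.cohort_compare(df, df.copy())
        assert (out.loc[["x0", "x1", "MADRS"], "p"] == 1.0).all()

    def test_recording_length_difference_significant(self):
        # groups with mean 9.9 sd 2.5 vs 6.7 sd 0.857, n=12 each
        def grp(mean, sd, n=12):
            base = np.resize([1.0, -1.0], n)
            base = (base - base.mean()) / base.std(ddof=1)
            return mean + sd * base
        t1 = pd.DataFrame({"rec_len": grp(9.9, 2.5)})
        t2 = pd.DataFrame({"rec_len": grp(6.7, 0.857)})
        out = a.cohort_compare(t1, t2)
        assert out.loc["rec_len", "p"] < 0.01
        tt = stats.ttest_ind(t1["rec_len"], t2["rec_len"], equal_var=True)
        assert out.loc["rec_len", "p"] == pytest.approx(tt.pvalue)

    def test_sex_ratio_chi_square(self):
        t1 = pd.DataFrame({"sex": [1] * 3 + [0] * 9})
        t2 = pd.DataFrame({"sex": [1] * 5 + [0] * 7})
        out = a.cohort_compare(t1, t2)
        assert out.loc["sex", "p"] == pytest.approx(0.39, abs=0.005)


class TestEndToEndRecovery:
    def test_validated_models_contain_true_predictors(self, cohort_pair,
                                                      brute_results):
        """Brute force + internal filter + external validation on 12+12
        synthetic cohorts recovers models built on the true predictors, and
        the achieved accuracy is far beyond the random-prediction null."""
        train, test = cohort_pair
        survivors, total = brute_results
        assert total == 14892
        r_min = a.critical_pearson_r(len(test))
        validated = [(m, r) for m in survivors
                     for r in [a.external_validate(m, test, r_min=r_min)]
                     if r.passed_external]
        assert validated
        true_hits = [m for m, _ in validated
                     if {"alpha_full", "IS5"} & set(m.predictors)]
        assert true_hits
        mean_rmse = float(np.mean([r.rmse for _, r in validated]))
        null = a.random_null(test["MADRS"], n_sim=100_000, seed=3)
        assert null.prob_at_most(mean_rmse) < 0.01

    def test_top10_recovery_rate_over_seeds(self):
        """Over 10 seeded 40-subject cohort pairs with two true predictors
        (standardized effects ~0.6/0.4, score noise sd 2), the ten most
        accurate externally validated models contain both true predictors in
        at least 8 of 10 replicates."""
        from conftest import COHORT_KW
        hits = 0
        for seed in range(10):
            tr = a.make_cohort(a.CohortSpec(n_subjects=40, seed=100 + seed,
                                            **COHORT_KW))
            te = a.make_cohort(a.CohortSpec(n_subjects=40, seed=200 + seed,
                                            **COHORT_KW))
            survivors, _ = a.brute_force(tr)
            r_min = a.critical_pearson_r(40)
            val = [(m, r) for m in survivors
                   for r in [a.external_validate(m, te, r_min=r_min)]
                   if r.passed_external]
            val.sort(key=lambda t: t[1].rmse)
            names = set().union(*[set(m.predictors) for m, _ in val[:10]]) \
                if val else set()
            hits += {"alpha_full", "IS5"} <= names
        assert hits >= 8
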