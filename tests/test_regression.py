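"""OLS fitting, AIC, VIF diagnostics, and forced-covariate backward elimination."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

import stabsel as ss
from conftest import make_simple_cohort


def _table(cols: dict, outcome: str = "y", forced=(), candidates=()) -> ss.CohortTable:
    meta = [ss.VariableMeta(outcome, "outcome", "continuous")]
    meta += [ss.VariableMeta(v, "forced", "continuous") for v in forced]
    meta += [ss.VariableMeta(v, "candidate", "continuous") for v in candidates]
    return ss.CohortTable(pd.DataFrame(cols), meta)


class TestFitOLS:
    def test_constant_outcome(self):
        t = _table({"y": [5.0] * 6, "x": [1.0, 2, 3, 4, 5, 6]}, candidates=("x",))
        fit = ss.fit_ols(t, ["x"], "y")
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-12)
        assert fit.params["const"] == pytest.approx(5.0)

    def test_perfect_fit(self):
        t = _table({"y": [2.0, 4, 6, 8, 10], "x": [1.0, 2, 3, 4, 5]}, candidates=("x",))
        fit = ss.fit_ols(t, ["x"], "y")
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        t = _table({"y": y + 6, "a": X[:, 0], "b": X[:, 1], "c": X[:, 2]},
                   candidates=("a", "b", "c"))
        fit = ss.fit_ols(t, ["a", "b", "c"], "y")
        D = np.column_stack([np.ones(20), X])
        oracle = np.linalg.solve(D.T @ D, D.T @ (y + 6))
        assert np.allclose(fit.params.to_numpy(), oracle, atol=1e-10)

    def test_rank_deficiency_lists_terms(self):
        x = np.arange(10.0)
        t = _table({"y": x + 6, "a": x, "b": 2 * x}, candidates=("a", "b"))
        with pytest.raises(ValueError, match="collinear"):
            ss.fit_ols(t, ["a", "b"], "y")

    def test_confidence_limits_bracket_estimate(self, small_cohort):
        fit = ss.fit_ols(small_cohort, ["age", "bmi", "stress"], "hba1c")
        assert (fit.conf_low <= fit.params).all() and (fit.params <= fit.conf_high).all()
        assert 0 <= fit.r2 <= 1 and fit.adj_r2 <= fit.r2


class TestAIC:
    def test_deterministic_in_rss_and_k(self):
        assert ss.aic_from_rss(50, 3, 12.5) == ss.aic_from_rss(50, 3, 12.5)

    def test_useless_parameter_costs_exactly_two(self):
        assert ss.aic_from_rss(50, 4, 12.5) - ss.aic_from_rss(50, 3, 12.5) == pytest.approx(2.0)

    def test_matches_gaussian_likelihood_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            X = rng.standard_normal((n, 2))
            y = X @ [1.0, -0.5] + rng.standard_normal(n) + 6
            t = _table({"y": y, "a": X[:, 0], "b": X[:, 1]}, candidates=("a", "b"))
            fit = ss.fit_ols(t, ["a", "b"], "y")
            # oracle: -2 * maximized Gaussian log-likelihood + 2k
            sigma2 = fit.rss / n
            llf = scipy.stats.norm.logpdf(fit.residuals, scale=np.sqrt(sigma2)).sum()
            assert fit.aic == pytest.approx(-2 * llf + 2 * fit.k, abs=1e-8)

    def test_perfect_fit_rejected(self):
        with pytest.raises(ValueError, match="RSS"):
            ss.aic_from_rss(10, 2, 0.0)


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        x1 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        x2 = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        t = _table({"y": np.arange(8) + 6.0, "a": x1, "b": x2}, candidates=("a", "b"))
        v = ss.vif(t, ["a", "b"])
        assert np.allclose(v, 1.0, atol=1e-10)

    def test_closed_form_at_r_09(self):
        # construct exact sample correlation 0.9: x2 = 0.9*x1 + sqrt(1-0.81)*e
        x1 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        e = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * e
        t = _table({"y": np.arange(8) + 6.0, "a": x1, "b": x2}, candidates=("a", "b"))
        v = ss.vif(t, ["a", "b"])
        assert np.allclose(v, 1 / (1 - 0.81), atol=1e-8)  # ~5.263

    def test_duplicated_column_infinite(self):
        x = np.array([1.0, 2, 3, 4, 5, 1, 2, 4])
        t = _table({"y": np.arange(8) + 6.0, "a": x, "b": x.copy()}, candidates=("a", "b"))
        v = ss.vif(t, ["a", "b"])
        assert np.isinf(v).all()

    def test_matches_statsmodels_on_cohort(self, small_cohort):
        terms = ["age", "bmi", "abdominal_circumference", "stress"]
        v = ss.vif(small_cohort, terms)
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        X = np.column_stack([np.ones(small_cohort.n)]
                            + [small_cohort.df[c] for c in terms])
        for j, name in enumerate(terms, start=1):
            assert v[name] == pytest.approx(variance_inflation_factor(X, j))

    def test_collinear_bmi_circumference_elevated(self, small_cohort):
        """The generator plants r=0.9 between BMI and abdominal circumference;
        their VIFs must stand out from the other covariates'."""
        terms = ["age", "bmi", "abdominal_circumference", "stress", "self_esteem"]
        v = ss.vif(small_cohort, terms)
        assert v["bmi"] > 3 and v["abdominal_circumference"] > 3
        assert v["age"] < 1.5 and v["stress"] < 1.5


class TestBackwardElimination:
    def test_no_candidates_nothing_to_do(self):
        t = make_simple_cohort(60, 0, seed=7)
        res = ss.backward_eliminate(t, ss.ModelSpec("y", forced=["xf"]))
        assert res.selected == ["xf"]
        assert res.elimination_path == []

    def test_forced_always_survive(self):
        t = make_simple_cohort(80, 5, seed=8, beta_forced=0.0)  # forced but useless
        res = ss.backward_eliminate(t, ss.ModelSpec.from_meta(t.meta))
        assert "xf" in res.selected

    def test_decision_matches_partial_p_threshold(self):
        """With a single candidate, the AIC keep/drop decision equals a
        likelihood-ratio test at p = P(chi2_1 > 2) ~ 0.157, across seeds."""
        threshold = scipy.stats.chi2.sf(2.0, df=1)  # 0.15729...
        both = {True: 0, False: 0}
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 60
            x = rng.standard_normal(n)
            c = rng.standard_normal(n)
            y = 6 + 0.5 * x + rng.uniform(0, 0.15) * c + rng.standard_normal(n)
            t = _table({"y": y, "xf": x, "c0": c}, forced=("xf",), candidates=("c0",))
            res = ss.backward_eliminate(t, ss.ModelSpec("y", ["xf"], ["c0"]))
            kept = "c0" in res.selected
            full = sm.OLS(y, np.column_stack([np.ones(n), x, c])).fit()
            restr = sm.OLS(y, np.column_stack([np.ones(n), x])).fit()
            lr = n * np.log(restr.ssr / full.ssr)
            p = scipy.stats.chi2.sf(lr, df=1)
            assert kept == (p < threshold)
            both[kept] += 1
        assert both[True] > 0 and both[False] > 0  # both branches exercised

    def test_path_aic_strictly_decreasing(self):
        t = make_simple_cohort(120, 8, seed=9, beta_cand=(0.8, 0.5))
        res = ss.backward_eliminate(t, ss.ModelSpec.from_meta(t.meta))
        for _, before, after in res.elimination_path:
            assert after < before
        global_fit = ss.fit_ols(t, ["xf"] + [f"c{j}" for j in range(8)], "y")
        assert res.fit.aic <= global_fit.aic

    def test_strong_candidates_survive(self):
        t = make_simple_cohort(200, 6, seed=10, beta_cand=(1.0, 0.9))
        res = ss.backward_eliminate(t, ss.ModelSpec.from_meta(t.meta))
        assert {"c0", "c1"} <= set(res.selected)

    def test_selection_invariant_to_candidate_order(self):
        t = make_simple_cohort(100, 6, seed=11, beta_cand=(0.7,))
        spec = ss.ModelSpec.from_meta(t.meta)
        shuffled = ss.ModelSpec("y", spec.forced, list(reversed(spec.candidates)))
        a = ss.backward_eliminate(t, spec)
        b = ss.backward_eliminate(t, shuffled)
        assert set(a.selected) == set(b.selected)

    def test_categorical_block_moves_together(self, small_cohort, small_spec):
        res = ss.backward_eliminate(small_cohort, small_spec)
        in_model = "census_region" in res.selected
        cols = set(res.fit.params.index)
        indicator_present = {"census_region[NWU]", "census_region[ROU]"} <= cols
        assert indicator_present == in_model
        removed = [name for name, _, _ in res.elimination_path]
        assert res.elimination_path and set(removed).isdisjoint(small_spec.forced)


class TestEstimatorAPI:
    def test_sklearn_params_round_trip(self):
        est = ss.BackwardEliminationOLS(forced=("xf",))
        assert est.get_params()["forced"] == ("xf",)
        est.set_params(forced=())
        assert est.get_params()["forced"] == ()

    def test_predict_matches_fitted_values(self):
        t = make_simple_cohort(80, 3, seed=12, beta_cand=(0.9,))
        X = t.df[["xf", "c0", "c1", "c2"]]
        y = t.df["y"].to_numpy()
        est = ss.BackwardEliminationOLS(forced=("xf",)).fit(X, y)
        yhat = est.predict(X)
        assert np.allclose(yhat, y - est.fit_result_.residuals, atol=1e-10)
        assert est.score(X, y) == pytest.approx(est.fit_result_.r2)
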