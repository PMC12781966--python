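"""Bootstrap stability metrics and the resampled selection procedure."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import stabsel as ss
from conftest import make_simple_cohort


class TestElementaryStatistics:
    def test_rmsd_zero_when_constant(self):
        assert ss.rmsd_ratio([1.2, 1.2, 1.2], 1.2, 0.5) == 0.0

    def test_rmsd_hand_value(self):
        assert ss.rmsd_ratio([0.0, 2.0], 1.0, 1.0) == pytest.approx(1.0)

    def test_rmsd_scale_invariance(self):
        b = np.array([0.1, -0.4, 0.7])
        r1 = ss.rmsd_ratio(b, 0.2, 0.3)
        r2 = ss.rmsd_ratio(7.0 * b, 7.0 * 0.2, 7.0 * 0.3)
        assert r1 == pytest.approx(r2)

    def test_rmsd_empty_errors(self):
        with pytest.raises(ValueError):
            ss.rmsd_ratio([], 1.0, 1.0)

    def test_rc_bias_unbiased_case(self):
        assert ss.rc_bias([1.0, 1.0], 1.0) == 0.0

    def test_rc_bias_hand_values(self):
        assert ss.rc_bias([1.5], 1.0) == pytest.approx(50.0)
        assert ss.rc_bias([-0.5], -1.0) == pytest.approx(-50.0)

    def test_rc_bias_undefined_cases(self):
        assert np.isnan(ss.rc_bias([1.0], 0.0))
        assert np.isnan(ss.rc_bias([], 1.0))

    def test_standardized_beta(self):
        assert ss.standardized_beta(0.7, 2.0, 2.0) == pytest.approx(0.7)
        assert ss.standardized_beta(0.0, 1.0, 3.0) == 0.0
        assert ss.standardized_beta(0.5, 4.0, 2.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ss.standardized_beta(1.0, 0.0, 1.0)

    def test_selected_model_frequency(self):
        ref = frozenset({"a", "b"})
        assert ss.selected_model_frequency([ref] * 10, ref) == 100.0
        assert ss.selected_model_frequency([frozenset({"a"})] * 10, ref) == 0.0
        sels = [ref] + [frozenset({"a"})] * 999
        assert ss.selected_model_frequency(sels, ref) == pytest.approx(0.1)


@pytest.fixture(scope="module")
def small_run(small_cohort, small_spec):
    return ss.bootstrap_stability(small_cohort, small_spec, B=150, seed=5)


class TestBootstrapRun:
    def test_forced_inclusion_is_exactly_100(self, small_run, small_spec):
        for v in small_spec.forced:
            assert small_run.summary.loc[v, "inclusion_frequency"] == 100.0

    def test_median_zero_rule(self, small_run):
        s = small_run.summary
        low = s[s.inclusion_frequency < 50]
        assert len(low) > 0
        assert (low.beta_b == 0.0).all()

    def test_majority_sign_rule(self, small_run):
        s = small_run.summary
        for var in s.index[s.inclusion_frequency > 50]:
            if var == "const":
                continue
            j = small_run.summary.index.get_loc(var)
            coefs = small_run.boot_coefs[:, j]
            nonzero = coefs[coefs != 0]
            majority = np.sign(np.median(np.sign(nonzero)))
            if majority != 0:
                assert np.sign(s.loc[var, "beta_b"]) in (0.0, majority)

    def test_percentile_sandwich(self, small_run):
        s = small_run.summary
        assert (s.pct_2_5 <= s.beta_b + 1e-12).all()
        assert (s.beta_b <= s.pct_97_5 + 1e-12).all()

    def test_block_columns_share_selection(self, small_run):
        s = small_run.summary
        a = s.loc["census_region[NWU]", "inclusion_frequency"]
        b = s.loc["census_region[ROU]", "inclusion_frequency"]
        assert a == b

    def test_reproducible_bit_identical(self, small_cohort, small_spec, small_run):
        again = ss.bootstrap_stability(small_cohort, small_spec, B=150, seed=5)
        assert again.identical(small_run)

    def test_different_seed_differs(self, small_cohort, small_spec, small_run):
        other = ss.bootstrap_stability(small_cohort, small_spec, B=150, seed=6)
        assert not other.identical(small_run)

    def test_oracle_resampling_loop(self):
        """Summaries agree with a hand-rolled statsmodels elimination loop fed
        the very same resample indices."""
        t = make_simple_cohort(40, 2, seed=13, beta_cand=(0.9,))
        spec = ss.ModelSpec.from_meta(t.meta)
        res = ss.bootstrap_stability(t, spec, B=12, seed=99)
        y_all = t.df["y"].to_numpy()
        cols = ["xf", "c0", "c1"]
        coefs = np.zeros((12, 4))  # const + 3 predictors
        for b, idx in enumerate(res.resample_indices):
            df = t.df.iloc[idx]
            yb = y_all[idx]
            active = list(cols)
            while True:
                X = np.column_stack([np.ones(len(df))] + [df[c] for c in active])
                aic_cur = sm.OLS(yb, X).fit().aic
                trials = []
                for c in [c for c in active if c != "xf"]:
                    rest = [v for v in active if v != c]
                    Xr = np.column_stack([np.ones(len(df))] + [df[v] for v in rest])
                    trials.append((sm.OLS(yb, Xr).fit().aic, c))
                if not trials or min(trials)[0] >= aic_cur:
                    break
                active.remove(min(trials)[1])
            X = np.column_stack([np.ones(len(df))] + [df[c] for c in active])
            beta = sm.OLS(yb, X).fit().params
            coefs[b, 0] = beta[0]
            for i, c in enumerate(cols, start=1):
                if c in active:
                    coefs[b, i] = beta[1 + active.index(c)]
        for i, name in enumerate(["const"] + cols):
            row = res.summary.loc[name]
            assert row.inclusion_frequency == pytest.approx(
                100.0 * np.mean(coefs[:, i] != 0) if name != "const" else 100.0)
            assert row.beta_b == pytest.approx(np.median(coefs[:, i]), abs=1e-8)
            lo, hi = np.percentile(coefs[:, i], [2.5, 97.5])
            assert row.pct_2_5 == pytest.approx(lo, abs=1e-8)
            assert row.pct_97_5 == pytest.approx(hi, abs=1e-8)

    def test_b_below_two_rejected(self, small_cohort, small_spec):
        with pytest.raises(ValueError, match="B"):
            ss.bootstrap_stability(small_cohort, small_spec, B=1, seed=0)


class TestShrinkage:
    def test_large_n_strong_signal_slope_near_one(self):
        t = make_simple_cohort(5000, 0, seed=14, beta_forced=1.0)
        sel = ss.backward_eliminate(t, ss.ModelSpec("y", forced=["xf"]))
        slope = ss.global_shrinkage(t, sel, folds=10, random_state=0)
        assert abs(slope - 1.0) < 0.05

    def test_pure_noise_model_slope_near_zero(self):
        slopes = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            n = 500
            df = pd.DataFrame({
                "y": rng.standard_normal(n) + 6,
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n),
            })
            meta = [ss.VariableMeta("y", "outcome", "continuous"),
                    ss.VariableMeta("x1", "forced", "continuous"),
                    ss.VariableMeta("x2", "forced", "continuous")]
            t = ss.CohortTable(df, meta)
            sel = ss.backward_eliminate(t, ss.ModelSpec("y", forced=["x1", "x2"]))
            slopes.append(ss.global_shrinkage(t, sel, folds=10, random_state=rep))
        # the calibration-slope ratio is heavy-tailed under the null (its
        # denominator is near zero), so summarise the replicates robustly
        assert abs(np.median(slopes)) < 0.15

    def test_noiseless_leave_one_out_slope_one(self):
        df = pd.DataFrame({"y": [2.0, 4, 6, 8], "x": [1.0, 2, 3, 4]})
        meta = [ss.VariableMeta("y", "outcome", "continuous"),
                ss.VariableMeta("x", "forced", "continuous")]
        t = ss.CohortTable(df, meta)
        sel = ss.backward_eliminate(t, ss.ModelSpec("y", forced=["x"]))
        assert ss.global_shrinkage(t, sel, folds=4, random_state=0) == pytest.approx(1.0)

    def test_constant_predictor_errors(self):
        df = pd.DataFrame({"y": [5.0, 6, 7, 8, 6, 5], "x": [1.0, 2, 3, 1, 2, 3]})
        meta = [ss.VariableMeta("y", "outcome", "continuous"),
                ss.VariableMeta("x", "forced", "continuous")]
        t = ss.CohortTable(df, meta)
        sel = ss.backward_eliminate(t, ss.ModelSpec("y", forced=["x"]))
        # degenerate folds request
        with pytest.raises(ValueError, match="folds"):
            ss.global_shrinkage(t, sel, folds=1)
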