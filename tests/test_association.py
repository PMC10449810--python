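import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from emphymap.association_pipeline import (
    DEFAULT_COVARIATES, adjusted_r2_gain, bh_adjust, correlation_matrix,
    estimate_ridge_k, fit_ridge, fit_univariate, likelihood_ratio_test,
    log_standardize, preprocess_biomarkers, run_ehp_biomarker_scan,
    standardize_metrics,
)
from emphymap.synthetic_data import CohortSpec, simulate_cohort


def covariate_frame(rng, n):
    return pd.DataFrame({
        "age": rng.normal(63, 9, n),
        "sex_male": rng.integers(0, 2, n),
        "bmi": rng.normal(28, 5, n),
        "height": rng.normal(170, 9, n),
        "smoker": rng.integers(0, 2, n),
    })


class TestTransforms:
    def test_log_standardize_mean_zero_sd_one(self, rng):
        res = log_standardize(rng.lognormal(1.0, 0.8, 500))
        assert res.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert res.values.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert res.offset == 0.0

    def test_zero_values_get_recorded_offset(self):
        res = log_standardize([0.0, 1.0, 2.0, 4.0])
        assert res.offset == pytest.approx(0.5)

    def test_negative_or_constant_errors(self):
        with pytest.raises(ValueError, match="nonnegative"):
            log_standardize([-1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            log_standardize([3.0, 3.0, 3.0])

    def test_log_transform_improves_normality_of_lognormal(self, rng):
        x = rng.lognormal(0.0, 1.0, 400)
        raw_p = stats.shapiro(x[:300]).pvalue
        z_p = stats.shapiro(log_standardize(x).values[:300]).pvalue
        assert z_p > raw_p

    def test_correlation_matrix_identities(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "neg": -x, "y": rng.normal(size=100)})
        pear, spear = correlation_matrix(df)
        assert pear.loc["x", "x"] == 1.0
        assert pear.loc["x", "neg"] == pytest.approx(-1.0)
        assert spear.loc["x", "neg"] == pytest.approx(-1.0)
        np.testing.assert_allclose(pear.to_numpy(), pear.to_numpy().T)

    def test_constant_column_errors(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            correlation_matrix(df)


class TestUnivariate:
    def test_recovers_strong_coefficient(self, rng):
        n = 400
        df = covariate_frame(rng, n)
        df["metric_z"] = rng.standard_normal(n)
        df["y"] = 2.0 * df["metric_z"] + rng.normal(0, 0.01, n)
        res = fit_univariate(df, "y", "metric_z")
        assert res.coefficient == pytest.approx(2.0, abs=0.01)
        assert res.r_squared > 0.99

    def test_duplicated_covariate_errors(self, rng):
        n = 50
        df = covariate_frame(rng, n)
        df["metric_z"] = rng.standard_normal(n)
        df["age2"] = df["age"]
        df["y"] = rng.standard_normal(n)
        with pytest.raises(ValueError, match="rank"):
            fit_univariate(df, "y", "metric_z",
                           covariates=(*DEFAULT_COVARIATES, "age2"))

    def test_too_few_rows_errors(self, rng):
        df = covariate_frame(rng, 5)
        df["metric_z"] = rng.standard_normal(5)
        df["y"] = rng.standard_normal(5)
        with pytest.raises(ValueError, match="few"):
            fit_univariate(df, "y", "metric_z")


class TestRidge:
    def _xy(self, rng, n=200, p=4, rho=0.6):
        cov = rho * np.ones((p, p)) + (1 - rho) * np.eye(p)
        X = rng.multivariate_normal(np.zeros(p), cov, n)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        beta = np.array([1.5, -1.0, 0.5, 0.0])
        y = X @ beta + rng.normal(0, 1.0, n)
        return X, y - y.mean()

    def test_hkb_matches_closed_form(self, rng):
        X, y = self._xy(rng)
        n, p = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - p - 1)
        expected = p * sigma2 / (beta @ beta)
        assert estimate_ridge_k(X, y, "hoerl_kennard_baldwin") == pytest.approx(
            expected, rel=1e-10)

    def test_huge_signal_gives_small_k(self, rng):
        n, p = 200, 3
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X @ np.array([50.0, -40.0, 30.0]) + rng.normal(0, 0.1, n)
        k = estimate_ridge_k(X, y - y.mean(), "kibria_gm")
        assert k < 1e-3

    def test_unknown_method_errors(self, rng):
        X, y = self._xy(rng)
        with pytest.raises(ValueError, match="unknown"):
            estimate_ridge_k(X, y, "unknown")

    def _ridge_frame(self, rng, n=150):
        df = covariate_frame(rng, n)
        for name in ("m1_z", "m2_z", "m3_z"):
            df[name] = rng.standard_normal(n)
        df["y"] = (1.2 * df["m1_z"] - 0.5 * df["m2_z"]
                   + 0.01 * df["age"] + rng.normal(0, 1, n))
        return df

    def test_k_zero_reduces_to_ols(self, rng):
        import statsmodels.api as sm
        df = self._ridge_frame(rng)
        metric_zs = ["m1_z", "m2_z", "m3_z"]
        rf = fit_ridge(df, "y", metric_zs, k=0.0)
        # OLS on the identically standardized design
        preds = [*metric_zs, *DEFAULT_COVARIATES]
        raw = df[preds].astype(float).to_numpy()
        Z = (raw - raw.mean(0)) / raw.std(0, ddof=1)
        fit = sm.OLS(df["y"] - df["y"].mean(), Z).fit()
        for i, term in enumerate(rf.terms):
            assert term.coefficient == pytest.approx(fit.params.iloc[i], abs=1e-10)

    def test_shrinkage_monotone_in_k(self, rng):
        df = self._ridge_frame(rng)
        norms = []
        for k in (0.0, 1.0, 10.0, 100.0, 1e4, 1e6):
            rf = fit_ridge(df, "y", ["m1_z", "m2_z", "m3_z"], k=k)
            norms.append(np.linalg.norm([t.coefficient for t in rf.terms]))
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_adjusted_r2_gain_identical_sets_zero(self, rng):
        df = self._ridge_frame(rng)
        full, red = adjusted_r2_gain(df, "y", ["m1_z", "m2_z"], ["m1_z", "m2_z"])
        assert full == red


class TestLRT:
    def test_identical_models_statistic_zero(self, rng):
        df = covariate_frame(rng, 80)
        df["y"] = rng.standard_normal(80)
        res = likelihood_ratio_test(df, "y", list(DEFAULT_COVARIATES),
                                    list(DEFAULT_COVARIATES))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_categorical_term_df(self, rng):
        n = 120
        df = covariate_frame(rng, n)
        df["va"] = pd.Categorical(rng.choice(list("abcdef"), n),
                                  categories=list("abcdef"))
        df["y"] = rng.standard_normal(n)
        res = likelihood_ratio_test(df, "y", [*DEFAULT_COVARIATES, "va"],
                                    list(DEFAULT_COVARIATES))
        assert res.df == 5

    def test_non_nested_errors(self, rng):
        df = covariate_frame(rng, 50)
        df["y"] = rng.standard_normal(50)
        with pytest.raises(ValueError, match="subset"):
            likelihood_ratio_test(df, "y", ["age", "bmi"], ["age", "height"])

    def test_logistic_family_detects_effect(self, rng):
        n = 400
        df = covariate_frame(rng, n)
        x = rng.standard_normal(n)
        df["x"] = x
        df["y"] = (rng.random(n) < 1 / (1 + np.exp(-1.5 * x))).astype(float)
        res = likelihood_ratio_test(df, "y", ["age", "x"], ["age"],
                                    family="logistic")
        assert res.p_value < 1e-6


class TestBiomarkers:
    def test_classification_rules(self, rng):
        n = 200
        raw = pd.DataFrame({
            "excl": rng.lognormal(0, 1, n),
            "binary": rng.lognormal(0, 1, n),
            "cont": rng.lognormal(0, 1, n),
        })
        lloq = pd.Series({
            "excl": float(np.quantile(raw["excl"], 0.97)),
            "binary": float(np.quantile(raw["binary"], 0.5)),
            "cont": 0.0,
        })
        panel = preprocess_biomarkers(raw, lloq)
        assert panel.classes["excl"] == "excluded"
        assert panel.classes["binary"] == "binary"
        assert panel.classes["cont"] == "continuous"
        assert set(panel.values["binary"].unique()) <= {0.0, 1.0}

    def test_quantile_transform_five_distinct_values(self):
        raw = pd.DataFrame({"m": [10.0, 20.0, 30.0, 40.0, 50.0]})
        panel = preprocess_biomarkers(raw, pd.Series({"m": 0.0}))
        expected = stats.norm.ppf([0.1, 0.3, 0.5, 0.7, 0.9])
        np.testing.assert_allclose(np.sort(panel.values["m"]), expected)

    def test_below_lloq_values_get_lowest_ranks(self):
        raw = pd.DataFrame({"m": [0.5, 0.2, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]})
        panel = preprocess_biomarkers(raw, pd.Series({"m": 1.0}))
        transformed = panel.values["m"]
        assert transformed[0] == transformed[1]  # tied at the bottom
        assert transformed[0] == transformed.min()

    def test_missing_lloq_errors(self):
        raw = pd.DataFrame({"m": [1.0, 2.0]})
        with pytest.raises(ValueError, match="LLOQ"):
            preprocess_biomarkers(raw, pd.Series(dtype=float))

    def test_scan_routes_acs_effect_to_ehp4(self):
        spec = CohortSpec(n_subjects=400,
                          biomarker_routes=["pp"] * 4 + ["null"] * 8,
                          biomarker_effect=0.5)
        sim = simulate_cohort(spec, seed=12)
        scan = run_ehp_biomarker_scan(sim.cohort, sim.biomarkers, sim.lloq)
        assert scan.n_ehp4_discoveries >= scan.n_ehp2_discoveries
        assert scan.n_ehp4_discoveries >= 3

    def test_scan_permutation_invariance(self):
        spec = CohortSpec(n_subjects=150, biomarker_routes=["pp", "shared", "null"])
        sim = simulate_cohort(spec, seed=5)
        scan = run_ehp_biomarker_scan(sim.cohort, sim.biomarkers, sim.lloq)
        shuffled = sim.biomarkers[list(sim.biomarkers.columns[::-1])]
        scan2 = run_ehp_biomarker_scan(sim.cohort, shuffled, sim.lloq)
        pd.testing.assert_frame_equal(scan.table.sort_index(),
                                      scan2.table.sort_index())


class TestBH:
    def test_toy_cases(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=40))
    def test_q_dominates_p_and_order_invariant(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2,
                    max_size=30))
    def test_discoveries_monotone_in_threshold(self, pvals):
        q = bh_adjust(np.array(pvals))
        d_05 = (q < 0.05).sum()
        d_10 = (q < 0.10).sum()
        d_20 = (q < 0.20).sum()
        assert d_05 <= d_10 <= d_20
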