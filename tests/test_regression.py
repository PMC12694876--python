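"""Regression-layer tests: fits, sandwich errors, battery, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import emocascade as ec
from emocascade.regression import (
    BATTERY_SPECS,
    DesignMatrix,
    InsufficientDataError,
    RankDeficiencyError,
    SmallClusterWarning,
    build_design,
    cluster_robust_se,
    fit_count_model,
    fit_ols,
)


def manual_design(X: pd.DataFrame, y, clusters, dv="cv") -> DesignMatrix:
    return DesignMatrix(
        response=np.asarray(y, dtype=float), X=X,
        clusters=np.asarray(clusters), dv=dv, min_size=2,
        include_emotions=True,
    )


@pytest.fixture(scope="module")
def sandwich_fixture():
    """30 rows, 3 clusters, heteroskedastic + cluster-correlated errors."""
    rng = np.random.default_rng(30)
    n, G = 30, 3
    clusters = np.repeat(["c1", "c2", "c3"], n // G)
    X = pd.DataFrame({
        "const": 1.0,
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
    })
    shocks = {g: rng.normal() for g in np.unique(clusters)}
    y = (1.0 + 0.5 * X["x1"] - 0.3 * X["x2"]
         + np.array([shocks[g] for g in clusters])
         + rng.normal(scale=0.5 + 0.5 * np.abs(X["x1"]), size=n))
    return manual_design(X, y, clusters)


class TestBuildDesign:
    def test_size_design_covers_all_cascades(self, small_scenario):
        feats = small_scenario["features"]
        design = build_design(feats, "size", min_size=2)
        assert design.n_obs == len(feats)
        assert design.X.columns[0] == "const"
        assert {f"emo_{e}" for e in ec.NON_NEUTRAL} <= set(design.X.columns)
        # neutral is the base: rows sum to at most one over emotion dummies
        emo = design.X[[f"emo_{e}" for e in ec.NON_NEUTRAL]]
        assert emo.sum(axis=1).max() <= 1.0

    def test_cv_design_drops_undefined_rows(self, small_scenario):
        feats = small_scenario["features"]
        design = build_design(feats, "cv", min_size=6)
        assert design.n_obs == int((feats["size"] >= 6).sum())
        assert np.isfinite(design.response).all()

    def test_neutral_only_dataset_has_no_emotion_dummies(self, small_scenario):
        feats = small_scenario["features"].copy()
        feats["dominant_emotion"] = "neutral"
        design = build_design(feats, "size", min_size=2)
        assert not any(c.startswith("emo_") for c in design.X.columns)
        assert set(design.dropped_columns) == {f"emo_{e}" for e in ec.NON_NEUTRAL}

    def test_size_response_variants(self, small_scenario):
        feats = small_scenario["features"]
        full = build_design(feats, "size", size_response="size").response
        excess = build_design(feats, "size", size_response="excess").response
        np.testing.assert_allclose(full - excess, 2.0)

    def test_single_cluster_insufficient(self, small_scenario):
        feats = small_scenario["features"]
        solo = feats[feats["event_label"] == "DC"]
        with pytest.raises(InsufficientDataError):
            build_design(solo, "size")


class TestCountModels:
    def test_poisson_parameter_recovery(self):
        rng = np.random.default_rng(1)
        n = 10_000
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        X = pd.DataFrame({"const": 1.0, "x": x})
        design = manual_design(X, y, np.tile(["a", "b", "c", "d"], n // 4), dv="size")
        fit = fit_count_model(design, family="poisson")
        for name, true in (("const", 1.0), ("x", 0.5)):
            assert abs(fit.params[name] - true) < 3 * fit.se_model[name]

    def test_nb_on_poisson_data_degenerates(self):
        # under equidispersion alpha-hat = 1/theta-hat sits at the zero
        # boundary up to half-normal noise of scale ~ sqrt(2/n)
        rng = np.random.default_rng(2)
        n = 4000
        y = rng.poisson(3.0, size=n)
        X = pd.DataFrame({"const": np.ones(n)})
        design = manual_design(X, y, np.tile(["a", "b"], n // 2), dv="size")
        nb = fit_count_model(design, family="negative_binomial")
        pois = fit_count_model(design, family="poisson")
        assert 1.0 / nb.theta < 3 * np.sqrt(2.0 / n)
        # NB nests Poisson; the LR statistic should be unremarkable
        assert nb.loglik >= pois.loglik - 1e-6
        assert 2 * (nb.loglik - pois.loglik) < 10.8  # chi2(1) 99.9th pct

    def test_intercept_only_nb_matches_sample_mean(self, small_scenario):
        feats = small_scenario["features"]
        y = (feats["size"] - 2).to_numpy(dtype=float)
        X = pd.DataFrame({"const": np.ones(len(y))})
        design = manual_design(X, y, feats["event_label"].to_numpy(), dv="size")
        fit = fit_count_model(design)
        assert np.exp(fit.params["const"]) == pytest.approx(y.mean(), rel=1e-6)

    def test_nb_nests_poisson_on_overdispersed_data(self, small_scenario):
        design = build_design(small_scenario["features"], "size",
                              size_response="excess")
        nb = fit_count_model(design, family="negative_binomial")
        pois = fit_count_model(design, family="poisson")
        assert nb.loglik >= pois.loglik - 1e-6
        assert nb.aic == pytest.approx(
            2 * (design.X.shape[1] + 1) - 2 * nb.loglik
        )

    def test_non_integer_response_rejected(self, small_scenario):
        design = build_design(small_scenario["features"], "cv", min_size=6)
        with pytest.raises(ValueError):
            fit_count_model(design)


class TestOLS:
    def test_exact_fit(self):
        X = pd.DataFrame({"const": np.ones(20), "x": np.arange(20.0)})
        y = 2.0 + 3.0 * X["x"]
        design = manual_design(X, y, np.tile(["a", "b"], 10))
        fit = fit_ols(design)
        np.testing.assert_allclose(fit.resid, 0.0, atol=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self, sandwich_fixture):
        fit = fit_ols(sandwich_fixture)
        A = sandwich_fixture.X.to_numpy()
        beta = np.linalg.pinv(A) @ sandwich_fixture.response
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_adjusted_r2_not_above_r2(self, small_scenario):
        design = build_design(small_scenario["features"], "log_lifetime")
        fit = fit_ols(design)
        res = sm.OLS(design.response, design.X).fit()
        assert fit.adj_r2 <= res.rsquared + 1e-12

    def test_rank_deficiency_names_columns(self, sandwich_fixture):
        X = sandwich_fixture.X.copy()
        X["x1_copy"] = X["x1"]
        design = manual_design(X, sandwich_fixture.response,
                               sandwich_fixture.clusters)
        with pytest.raises(RankDeficiencyError, match="x1"):
            fit_ols(design)


def oracle_cluster_cov(X, resid, clusters):
    """Brute-force CR1 sandwich for OLS, written independently."""
    A = X.to_numpy(dtype=float)
    n, k = A.shape
    bread = np.linalg.inv(A.T @ A)
    meat = np.zeros((k, k))
    for g in np.unique(clusters):
        rows = np.flatnonzero(clusters == g)
        s = np.zeros(k)
        for i in rows:
            s = s + A[i] * resid[i]
        meat += np.outer(s, s)
    G = len(np.unique(clusters))
    c = G / (G - 1) * (n - 1) / (n - k)
    return c * bread @ meat @ bread


class TestClusterRobust:
    def test_matches_bruteforce_oracle(self, sandwich_fixture):
        fit = fit_ols(sandwich_fixture)
        with pytest.warns(SmallClusterWarning):
            fit = cluster_robust_se(fit, sandwich_fixture)
        cov = oracle_cluster_cov(
            sandwich_fixture.X, fit.resid, sandwich_fixture.clusters
        )
        np.testing.assert_allclose(
            fit.se_cluster.to_numpy(), np.sqrt(np.diag(cov)), atol=1e-8
        )

    def test_matches_statsmodels_cluster(self, sandwich_fixture):
        fit = fit_ols(sandwich_fixture)
        with pytest.warns(SmallClusterWarning):
            fit = cluster_robust_se(fit, sandwich_fixture)
        codes = pd.factorize(sandwich_fixture.clusters)[0]
        res = sm.OLS(sandwich_fixture.response, sandwich_fixture.X).fit(
            cov_type="cluster", cov_kwds={"groups": codes}
        )
        np.testing.assert_allclose(fit.se_cluster.to_numpy(), res.bse, rtol=1e-8)

    def test_singleton_clusters_reduce_to_hc1(self, sandwich_fixture):
        design = manual_design(
            sandwich_fixture.X, sandwich_fixture.response,
            np.arange(len(sandwich_fixture.response)).astype(str),
        )
        fit = fit_ols(design)
        fit = cluster_robust_se(fit, design)
        res = sm.OLS(design.response, design.X).fit(cov_type="HC1")
        np.testing.assert_allclose(fit.se_cluster.to_numpy(), res.bse, rtol=1e-8)

    def test_duplicating_rows_keeps_t_ratios(self, sandwich_fixture):
        fit = fit_ols(sandwich_fixture)
        with pytest.warns(SmallClusterWarning):
            fit = cluster_robust_se(fit, sandwich_fixture)
        X2 = pd.concat([sandwich_fixture.X] * 2, ignore_index=True)
        y2 = np.concatenate([sandwich_fixture.response] * 2)
        cl2 = np.concatenate([sandwich_fixture.clusters] * 2)
        design2 = manual_design(X2, y2, cl2)
        fit2 = fit_ols(design2)
        with pytest.warns(SmallClusterWarning):
            fit2 = cluster_robust_se(fit2, design2)
        t1 = (fit.params / fit.se_cluster).to_numpy()
        t2 = (fit2.params / fit2.se_cluster).to_numpy()
        np.testing.assert_allclose(t2, t1, rtol=0.02)

    def test_single_cluster_rejected(self, sandwich_fixture):
        design = manual_design(
            sandwich_fixture.X, sandwich_fixture.response,
            np.repeat("only", len(sandwich_fixture.response)),
        )
        fit = fit_ols(design)
        with pytest.raises(InsufficientDataError):
            cluster_robust_se(fit, design)

    def test_glm_sandwich_positive_and_finite(self, small_scenario):
        design = build_design(small_scenario["features"], "size",
                              size_response="excess")
        fit = fit_count_model(design)
        with pytest.warns(SmallClusterWarning):
            fit = cluster_robust_se(fit, design)
        assert (fit.se_cluster > 0).all()
        assert np.isfinite(fit.se_cluster.to_numpy()).all()


@pytest.fixture(scope="module")
def fits(small_scenario):
    return ec.run_model_battery(small_scenario["features"])


class TestBattery:
    def test_enumerates_fourteen_fits(self, fits):
        assert len(fits) == 2 * len(BATTERY_SPECS)
        labels = {f.label() for f in fits}
        assert len(labels) == 14

    def test_shared_control_naming(self, fits):
        from emocascade.regression import CONTROL_COLUMNS
        for fit in fits:
            assert set(CONTROL_COLUMNS) <= set(fit.params.index)

    def test_cluster_errors_attached(self, fits):
        assert all(f.se_cluster is not None for f in fits)
        assert all(f.n_clusters == 4 for f in fits)

    def test_bit_reproducible(self, small_scenario, fits):
        again = ec.run_model_battery(small_scenario["features"])
        for a, b in zip(fits, again):
            pd.testing.assert_series_equal(a.params, b.params)

    def test_sign_pattern_shape(self, fits):
        pattern = ec.sign_pattern(fits)
        assert list(pattern.columns) == ["size", "lifetime", "speed", "burstiness"]
        assert set(pattern.index) == set(ec.NON_NEUTRAL)
        assert pattern.isin(["+", "-", "0"]).all().all()


class TestSignPatternLogic:
    def _fit(self, dv, min_size, coef, pval):
        names = ["const"] + [f"emo_{e}" for e in ec.NON_NEUTRAL]
        params = pd.Series(0.0, index=names)
        pvals = pd.Series(1.0, index=names)
        params["emo_disgust"] = coef
        pvals["emo_disgust"] = pval
        return ec.FitResult(
            dv=dv, family="ols", min_size=min_size, include_emotions=True,
            params=params, se_model=params * 0 + 1.0, pvalues_model=pvals,
            n_obs=100, se_cluster=params * 0 + 1.0, pvalues_cluster=pvals,
            n_clusters=4,
        )

    def test_signs_and_speed_inversion(self):
        fits = [
            self._fit("size", 2, 0.8, 0.01),
            self._fit("log_lifetime", 2, 0.5, 0.20),
            self._fit("log_median_delay", 6, -0.4, 0.001),
            self._fit("cv", 6, 0.6, 0.04),
        ]
        pattern = ec.sign_pattern(fits, alpha=0.05)
        assert pattern.loc["disgust", "size"] == "+"
        assert pattern.loc["disgust", "lifetime"] == "0"  # not significant
        assert pattern.loc["disgust", "speed"] == "+"  # negative delay = faster
        assert pattern.loc["disgust", "burstiness"] == "+"
        assert (pattern.drop(index="disgust") == "0").all().all()


class TestRecoverySmoke:
    def test_report_structure(self):
        config = ec.ScenarioConfig.recovery(n_cascades=600, seed=2)
        report = ec.recovery_experiment(config, n_reps=3, seed=2)
        assert report.n_reps == 3
        assert set(report.coefficients.index) == {f"emo_{e}" for e in ec.NON_NEUTRAL}
        assert np.isfinite(report.coefficients[["bias", "sd"]].to_numpy()).all()
        assert 0.0 <= report.pooled_coverage95 <= 1.0
        payload = report.to_dict()
        assert payload["n_cascades"] == 600
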