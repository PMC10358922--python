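import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from screenvar.broad_models import (
    fit_rate_model,
    lrt_nb_vs_poisson,
    marginal_sprr,
    wald_tests,
)
from screenvar.standardization import ScreeningCounts


def _toy_inputs(y, E, areas_extra=None):
    n = len(y)
    ids = [f"a{i}" for i in range(n)]
    counts = ScreeningCounts(area=pd.DataFrame({
        "area_id": ids, "period": "p",
        "invitees": (np.asarray(E) * 3).astype(int) + np.asarray(y, int),
        "screened": y}))
    expected = pd.DataFrame({"area_id": ids, "period": "p", "expected": E})
    areas = pd.DataFrame({"area_id": ids, **(areas_extra or {})})
    return counts, expected, areas


class TestFitRateModel:
    def test_null_model_calibration(self, null_system):
        """Intercept-only fit on internally calibrated data: PRR ~ 1."""
        from screenvar.standardization import compute_spr
        fit = fit_rate_model(null_system["counts"], null_system["expected"],
                             null_system["areas"], family="poisson",
                             covariates=[])
        assert fit.params["Intercept"] == pytest.approx(0.0, abs=0.01)
        assert fit.prr["prr"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_intercept_only_poisson_has_closed_form(self):
        """beta0_hat = log(sum y / sum E) for the offset-only Poisson."""
        y = np.array([120, 80, 95])
        E = np.array([100.0, 90.0, 100.0])
        counts, expected, areas = _toy_inputs(y, E)
        fit = fit_rate_model(counts, expected, areas, family="poisson",
                             covariates=[])
        assert fit.params["Intercept"] == pytest.approx(
            np.log(y.sum() / E.sum()), abs=1e-8)

    def test_three_area_toy_matches_brute_force_likelihood(self):
        """Coefficients agree with direct numerical maximisation of the
        Poisson log-likelihood to 3 decimals."""
        y = np.array([50, 30, 90])
        E = np.array([40.0, 35.0, 70.0])
        grp = {"remoteness": ["major_cities", "remote", "major_cities"]}
        counts, expected, areas = _toy_inputs(y, E, grp)
        fit = fit_rate_model(counts, expected, areas, family="poisson",
                             covariates=["remoteness"])

        X = np.column_stack([np.ones(3), np.array([0, 1, 0.0])])

        def nll(beta):
            eta = X @ beta + np.log(E)
            return -(y @ eta - np.exp(eta).sum())

        res = optimize.minimize(nll, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        np.testing.assert_allclose(
            fit.params[["Intercept", "remoteness[remote]"]], res.x, atol=1e-3)

    def test_nb_with_vanishing_dispersion_matches_poisson(self, null_system):
        """On equidispersed data the NB fit collapses onto Poisson."""
        pois = fit_rate_model(null_system["counts"], null_system["expected"],
                              null_system["areas"], family="poisson")
        nb = fit_rate_model(null_system["counts"], null_system["expected"],
                            null_system["areas"], family="negative_binomial")
        assert nb.dispersion < 1e-3
        common = pois.params.index
        np.testing.assert_allclose(nb.params[common], pois.params[common],
                                   atol=1e-4)

    def test_offset_invariance(self, small_system):
        """Doubling every E leaves all PRRs unchanged and shifts only the
        intercept by -log 2."""
        fit1 = fit_rate_model(small_system["counts"], small_system["expected"],
                              small_system["areas"], family="poisson")
        doubled = small_system["expected"].copy()
        doubled["expected"] *= 2
        fit2 = fit_rate_model(small_system["counts"], doubled,
                              small_system["areas"], family="poisson")
        terms = [t for t in fit1.coef_terms if t != "Intercept"]
        np.testing.assert_allclose(fit1.params[terms], fit2.params[terms],
                                   atol=1e-6)
        assert fit2.params["Intercept"] - fit1.params["Intercept"] == pytest.approx(
            -np.log(2), abs=1e-6)

    def test_zero_expected_rejected(self):
        counts, expected, areas = _toy_inputs(np.array([5, 5]), np.array([5.0, 5.0]))
        expected.loc[0, "expected"] = 0.0
        with pytest.raises(ValueError, match="positive expected"):
            fit_rate_model(counts, expected, areas, covariates=[])


class TestLRT:
    def test_identical_loglik_gives_stat_zero_p_one(self, null_system):
        nb = fit_rate_model(null_system["counts"], null_system["expected"],
                            null_system["areas"], family="negative_binomial",
                            covariates=[])
        pois = fit_rate_model(null_system["counts"], null_system["expected"],
                              null_system["areas"], family="poisson",
                              covariates=[])
        nb_same = nb
        object.__setattr__(nb_same, "loglik", pois.loglik)
        stat, p = lrt_nb_vs_poisson(nb_same, pois)
        assert stat == 0.0
        assert p == 1.0

    def test_mismatched_data_rejected(self, null_system, small_system):
        nb = fit_rate_model(small_system["counts"], small_system["expected"],
                            small_system["areas"], family="negative_binomial",
                            covariates=[])
        pois = fit_rate_model(null_system["counts"], null_system["expected"],
                              null_system["areas"], family="poisson",
                              covariates=[])
        with pytest.raises(ValueError, match="same data"):
            lrt_nb_vs_poisson(nb, pois)

    def test_overdispersed_data_strongly_rejects_poisson(self):
        """NB data with substantial dispersion: the boundary LRT should
        find the Poisson fit inadequate."""
        rng = np.random.default_rng(3)
        n, alpha = 300, 0.5
        E = np.full(n, 200.0)
        g = rng.gamma(1 / alpha, alpha, size=n)
        y = rng.poisson(E * g)
        counts, expected, areas = _toy_inputs(y, E)
        nb = fit_rate_model(counts, expected, areas,
                            family="negative_binomial", covariates=[])
        pois = fit_rate_model(counts, expected, areas, family="poisson",
                              covariates=[])
        stat, p = lrt_nb_vs_poisson(nb, pois)
        assert p < 1e-6
        assert nb.dispersion == pytest.approx(alpha, rel=0.3)


class TestWald:
    def test_single_term_group_equals_squared_z(self, small_system):
        fit = fit_rate_model(small_system["counts"], small_system["expected"],
                             small_system["areas"], family="poisson")
        term = "remoteness[remote]"
        out = wald_tests(fit, {"solo": [term]})
        z = fit.params[term] / np.sqrt(fit.cov.loc[term, term])
        p_group = float(stats.chi2.sf(z**2, 1))
        assert out["solo"] == pytest.approx(p_group, rel=1e-10)
        assert out[term] == pytest.approx(p_group, rel=1e-6)

    def test_null_coefficient_has_p_one(self):
        """A coefficient of exactly zero with positive variance: p = 1."""
        from screenvar.broad_models import GLMResult
        params = pd.Series({"Intercept": 0.0, "x[b]": 0.0})
        cov = pd.DataFrame(np.eye(2) * 0.04, index=params.index,
                           columns=params.index)
        fit = GLMResult(family="poisson", params=params, cov=cov,
                        dispersion=0.0, loglik=0.0, prr=pd.DataFrame(),
                        data=pd.DataFrame(), design=pd.DataFrame(),
                        offset=np.zeros(1), y=np.zeros(1),
                        covariates=("x",), references={"x": "a"})
        out = wald_tests(fit)
        assert out["x[b]"] == 1.0


class TestMarginalSPRR:
    def test_single_covariate_marginal_equals_conditional(self, small_system):
        fit = fit_rate_model(small_system["counts"], small_system["expected"],
                             small_system["areas"], family="poisson",
                             covariates=["remoteness"])
        marg = marginal_sprr(fit, "remoteness").set_index("stratum")
        for term in fit.coef_terms:
            if term.startswith("remoteness["):
                level = term.split("[")[1][:-1]
                assert marg.loc[level, "sprr"] == pytest.approx(
                    np.exp(fit.params[term]), rel=1e-8)
        assert marg.loc[fit.references["remoteness"], "sprr"] == 1.0

    def test_orthogonal_design_marginal_close_to_conditional(self):
        """With balanced, independent covariates the predictive margin
        approximates the conditional PRR."""
        rng = np.random.default_rng(5)
        n = 2000
        a = np.repeat(["x", "y"], n // 2)
        b = np.tile(["u", "v"], n // 2)
        E = np.full(n, 150.0)
        eta = np.log(0.8) * (a == "y") + np.log(1.3) * (b == "v")
        y = rng.poisson(E * np.exp(eta))
        counts, expected, areas = _toy_inputs(y, E, {"grp_a": a, "grp_b": b})
        fit = fit_rate_model(counts, expected, areas, family="poisson",
                             covariates=["grp_a", "grp_b"])
        marg = marginal_sprr(fit, "grp_a").set_index("stratum")
        assert marg.loc["y", "sprr"] == pytest.approx(
            np.exp(fit.params["grp_a[y]"]), rel=0.01)

    def test_strong_deficit_detected_with_ci_excluding_one(self):
        """A stratum with true rate ratio 0.6 yields SPRR < 1 with a CI
        excluding 1 at moderate size."""
        rng = np.random.default_rng(6)
        n = 400
        state = np.where(np.arange(n) % 10 == 0, "nt_like", "big_state")
        E = np.full(n, 300.0)
        y = rng.poisson(E * np.where(state == "nt_like", 0.6, 1.0))
        counts, expected, areas = _toy_inputs(y, E, {"state": state})
        fit = fit_rate_model(counts, expected, areas, family="poisson",
                             covariates=["state"])
        marg = marginal_sprr(fit, "state").set_index("stratum")
        assert marg.loc["nt_like", "sprr"] < 1
        assert marg.loc["nt_like", "ci_high"] < 1
        assert marg.loc["nt_like", "sprr"] == pytest.approx(0.6, abs=0.05)

    def test_unknown_factor_rejected(self, small_system):
        fit = fit_rate_model(small_system["counts"], small_system["expected"],
                             small_system["areas"], family="poisson",
                             covariates=["remoteness"])
        with pytest.raises(ValueError):
            marginal_sprr(fit, "disadvantage")
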