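"""The four regression families against independent oracles."""

import numpy as np
import pytest
from scipy import optimize, special, stats
from statsmodels.discrete.discrete_model import Probit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from prefmap.estimators import (
    FitError,
    FittedModel,
    fit_beta_mixture,
    fit_ols,
    fit_ordered_probit,
    fit_tobit,
    load_model,
    predict_direct,
    save_model,
)
from prefmap.synthetic_cohort import TruthModel, generate_from_truth
from conftest import make_design


class TestOls:
    def test_exact_linear_fit(self):
        X = make_design({"x": np.arange(10.0)})
        y = 0.2 + 0.05 * np.arange(10.0)
        model = fit_ols(X, y)
        assert model.extras["sigma"] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(predict_direct(model, X), y, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = make_design({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        y = rng.normal(size=50)
        model = fit_ols(X, y)
        beta_oracle = np.linalg.pinv(X.values) @ y
        np.testing.assert_allclose(model.beta, beta_oracle, atol=1e-8)

    def test_fitted_mean_identity(self, cohort):
        from prefmap.design import build_design

        X = build_design(cohort, "M1")
        y = cohort["utility"].to_numpy()
        model = fit_ols(X, y)
        at_mean = make_design({"total": [cohort["total"].mean()]})
        assert predict_direct(model, at_mean)[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_residuals_orthogonal_to_design(self, cohort):
        from prefmap.design import build_design

        X = build_design(cohort, "M4")
        y = cohort["utility"].to_numpy()
        model = fit_ols(X, y)
        resid = y - predict_direct(model, X)
        assert np.abs(X.values.T @ resid).max() < 1e-6 * X.n

    def test_loglik_matches_independent_reevaluation(self, cohort):
        from prefmap.design import build_design

        X = build_design(cohort, "M3")
        y = cohort["utility"].to_numpy()
        model = fit_ols(X, y)
        resid = y - X.values @ model.beta
        sigma2 = np.mean(resid**2)
        ll = -0.5 * X.n * (np.log(2 * np.pi * sigma2) + 1)
        assert model.loglik == pytest.approx(ll, abs=1e-8)

    def test_rank_deficiency_reported(self):
        x = np.arange(8.0)
        X = make_design({"x": x, "x2": 2 * x})
        with pytest.raises(FitError, match="rank"):
            fit_ols(X, np.ones(8))


class TestTobit:
    def test_reduces_to_ols_without_censoring(self):
        rng = np.random.default_rng(2)
        X = make_design({"x": rng.normal(size=400)})
        y = 0.5 + 0.1 * X.values[:, 1] + 0.05 * rng.normal(size=400)
        y = np.minimum(y, 0.999)  # nothing at the bound
        ols, tobit = fit_ols(X, y), fit_tobit(X, y, compute_se=False)
        np.testing.assert_allclose(ols.beta, tobit.beta, atol=1e-4)

    def test_loglik_at_optimum_beats_ols_start(self):
        rng = np.random.default_rng(3)
        X = make_design({"x": rng.normal(size=600)})
        y = np.minimum(0.9 + 0.1 * X.values[:, 1] + 0.1 * rng.normal(size=600), 1.0)
        tobit = fit_tobit(X, y, compute_se=False)
        ols = fit_ols(X, y)
        assert tobit.loglik >= _tobit_loglik(
            X.values, y, ols.beta, ols.extras["sigma"]
        ) - 1e-8

    def test_loglik_matches_independent_reevaluation(self):
        rng = np.random.default_rng(4)
        X = make_design({"x": rng.normal(size=500)})
        y = np.minimum(0.85 + 0.1 * X.values[:, 1] + 0.1 * rng.normal(size=500), 1.0)
        model = fit_tobit(X, y, compute_se=False)
        ll = _tobit_loglik(X.values, y, model.beta, model.extras["sigma"])
        assert model.loglik == pytest.approx(ll, abs=1e-8)

    def test_all_censored_rejected(self):
        X = make_design({"x": np.zeros(10)})
        with pytest.raises(FitError, match="censored"):
            fit_tobit(X, np.ones(10))

    def test_censored_expectation_below_latent_index(self):
        rng = np.random.default_rng(5)
        X = make_design({"x": rng.normal(size=300)})
        y = np.minimum(0.9 + 0.1 * X.values[:, 1] + 0.1 * rng.normal(size=300), 1.0)
        model = fit_tobit(X, y, compute_se=False)
        latent = predict_direct(model, X)
        censored = predict_direct(model, X, censored_expectation=True)
        assert np.all(censored <= latent + 1e-10)
        assert np.all(censored <= 1.0 + 1e-10)


def _tobit_loglik(X, y, beta, sigma, upper=1.0):
    eta = X @ beta
    cens = y >= upper
    ll = stats.norm.logpdf(y[~cens], eta[~cens], sigma).sum()
    ll += stats.norm.logsf(upper, eta[cens], sigma).sum()
    return ll


class TestOrderedProbit:
    def test_intercept_only_closed_form(self):
        X = make_design({"zero": np.zeros(1000)}, intercept=False)
        levels = np.repeat([1, 2, 3], [200, 300, 500])
        model = fit_ordered_probit(X, levels, compute_se=False)
        np.testing.assert_allclose(
            model.extras["cutpoints"], stats.norm.ppf([0.2, 0.5]), atol=1e-6
        )

    def test_matches_statsmodels_ordered_model(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=600)
        X = make_design({"x": x}, intercept=False)
        truth = TruthModel("oprobit", {"beta": {"x": 0.8}, "cutpoints": [-1.0, 0.2, 1.1]})
        levels = generate_from_truth(truth, X, seed=7)
        model = fit_ordered_probit(X, levels, compute_se=False)
        sm_fit = OrderedModel(levels, x[:, None], distr="probit").fit(
            method="bfgs", disp=0
        )
        assert model.coefficients["x"] == pytest.approx(sm_fit.params[0], abs=1e-4)
        assert model.loglik == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_binary_case_equals_probit_regression(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=800)
        X = make_design({"x": x}, intercept=False)
        truth = TruthModel("oprobit", {"beta": {"x": 0.6}, "cutpoints": [0.3]})
        levels = generate_from_truth(truth, X, seed=9)
        model = fit_ordered_probit(X, levels, compute_se=False)
        # P(level 2) = Phi(x b - k): probit on the dichotomised response with
        # intercept -k
        sm_fit = Probit((levels == 2).astype(int), np.column_stack([np.ones(800), x])).fit(disp=0)
        assert model.coefficients["x"] == pytest.approx(sm_fit.params[1], abs=1e-5)
        assert -model.extras["cutpoints"][0] == pytest.approx(sm_fit.params[0], abs=1e-5)

    def test_empty_category_collapsed_with_warning(self):
        X = make_design({"x": np.linspace(-1, 1, 300)}, intercept=False)
        levels = np.where(np.arange(300) % 2 == 0, 1, 4)  # levels 2,3 unobserved
        with pytest.warns(UserWarning, match="collapsed"):
            model = fit_ordered_probit(X, levels, compute_se=False)
        assert model.extras["n_categories"] == 2
        assert model.extras["level_map"] == {"1": 0, "4": 1}

    def test_loglik_matches_independent_reevaluation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=400)
        X = make_design({"x": x}, intercept=False)
        truth = TruthModel("oprobit", {"beta": {"x": 0.5}, "cutpoints": [-0.5, 0.7]})
        levels = generate_from_truth(truth, X, seed=11)
        model = fit_ordered_probit(X, levels, compute_se=False)
        cut = np.concatenate([[-np.inf], model.extras["cutpoints"], [np.inf]])
        eta = x * model.coefficients["x"]
        probs = stats.norm.cdf(cut[levels] - eta) - stats.norm.cdf(cut[levels - 1] - eta)
        assert model.loglik == pytest.approx(np.log(probs).sum(), abs=1e-8)


class TestBetaMixture:
    def test_single_component_matches_beta_regression_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=500)
        X = make_design({"x": x})
        mu = special.expit(0.4 + 0.5 * x)
        z = rng.beta(mu * 10, (1 - mu) * 10)
        y = 0.315 + (1 - 0.315) * z
        model = fit_beta_mixture(X, y, components=1, mass_at_ub=False, n_starts=3)

        def oracle_negll(p):
            m = special.expit(X.values @ p[:2])
            phi = np.exp(p[2])
            return -stats.beta.logpdf(z, m * phi, (1 - m) * phi).sum()

        res = optimize.minimize(
            oracle_negll, [0.0, 0.0, 2.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        np.testing.assert_allclose(
            model.extras["beta_components"][0], res.x[:2], atol=1e-4
        )
        # reported loglik includes the utility-scale change of variable
        assert model.loglik == pytest.approx(
            -res.fun - 500 * np.log(1 - 0.315), abs=1e-4
        )

    def test_predictions_within_bounds_and_monotone_in_mass(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=400)
        X = make_design({"x": x})
        truth = TruthModel(
            "betamix",
            {
                "beta_components": [[0.2, 0.4]],
                "lnphi": [2.3],
                "mixing_probs": [1.0],
                "mass_coefficients": {"const": -2.5, "x": 0.5},
                "bounds": (0.315, 1.0),
            },
        )
        y = generate_from_truth(truth, X, seed=14)
        model = fit_beta_mixture(X, y, components=1, n_starts=3)
        pred = predict_direct(model, X)
        assert np.all(pred >= 0.315 - 1e-9) and np.all(pred <= 1 + 1e-9)
        # raising the mass probability moves the prediction toward 1
        boosted = FittedModel.from_dict(model.to_dict())
        boosted.extras["mass_coefficients"] = dict(model.extras["mass_coefficients"])
        boosted.extras["mass_coefficients"]["const"] += 1.0
        assert np.all(predict_direct(boosted, X) >= pred - 1e-12)

    def test_no_mass_prediction_is_rescaled_mixture_mean(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=200)
        X = make_design({"x": x})
        mu = special.expit(0.1 + 0.3 * x)
        z = rng.beta(mu * 15, (1 - mu) * 15)
        y = 0.315 + (1 - 0.315) * z
        model = fit_beta_mixture(X, y, components=1, mass_at_ub=False, n_starts=2)
        pred = predict_direct(model, X)
        b = np.asarray(model.extras["beta_components"][0])
        expected = 0.315 + (1 - 0.315) * special.expit(X.values @ b)
        np.testing.assert_allclose(pred, expected, atol=1e-12)

    def test_all_at_ceiling_flagged_degenerate(self):
        X = make_design({"x": np.zeros(20)})
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_beta_mixture(X, np.ones(20), components=1)
        assert not model.converged
        assert model.extras["mass_probability"] == 1.0

    def test_truncated_variant_uses_0965_bound(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=300)
        X = make_design({"x": x})
        mu = special.expit(0.2 + 0.3 * x)
        z = rng.beta(mu * 10, (1 - mu) * 10)
        y = 0.315 + (0.965 - 0.315) * z
        model = fit_beta_mixture(X, y, components=1, mass_at_ub=False, truncated=True, n_starts=2)
        assert model.extras["bounds"] == [0.315, 0.965]

    def test_boundary_value_instructs_bound_adjustment(self):
        X = make_design({"x": np.zeros(10)})
        y = np.full(10, 0.5)
        y[0] = 0.315  # exactly at the lower bound
        with pytest.raises(FitError, match="bound"):
            fit_beta_mixture(X, y, components=1, mass_at_ub=False)

    def test_component_relabelling_orders_means(self):
        rng = np.random.default_rng(17)
        X = make_design({"x": rng.normal(size=3000)})
        truth = TruthModel(
            "betamix",
            {
                "beta_components": [[-1.0, 0.2], [1.2, 0.2]],
                "lnphi": [3.0, 3.0],
                "mixing_probs": [0.5, 0.5],
                "mass_coefficients": None,
                "bounds": (0.315, 1.0),
            },
        )
        truth.params["mass_coefficients"] = None
        y = generate_from_truth(truth, X, seed=18)
        model = fit_beta_mixture(X, y, components=2, mass_at_ub=False, n_starts=6)
        b = np.asarray(model.extras["beta_components"])
        means = [special.expit(X.values @ bc).mean() for bc in b]
        assert means[0] < means[1]


class TestSerialization:
    def test_round_trip_identical_predictions(self, tmp_path, cohort_small):
        from prefmap.design import build_design

        X = build_design(cohort_small, "M2")
        y = cohort_small["utility"].to_numpy()
        model = fit_ols(X, y, spec_id="M2")
        path = tmp_path / "m.json"
        save_model(model, path)
        reloaded = load_model(path)
        np.testing.assert_allclose(
            predict_direct(model, X), predict_direct(reloaded, X), atol=1e-12
        )
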