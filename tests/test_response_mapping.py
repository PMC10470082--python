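"""Indirect mapping: per-dimension ordered probits -> expected utility."""

import numpy as np
import pytest
from scipy import stats

from prefmap.design import build_design
from prefmap.instruments import SF6D_LEVEL_COUNTS, Tariff
from prefmap.response_mapping import (
    ResponseModelSet,
    expected_utility,
    fit_response_mapping,
    level_probabilities,
    predict_expected_utilities,
)
from prefmap.synthetic_cohort import SimConfig, generate_cohort
from conftest import make_design


def _random_prob_vectors(rng, n=1):
    probs = []
    for count in SF6D_LEVEL_COUNTS:
        p = rng.dirichlet(np.ones(count), size=n)
        probs.append(p)
    return probs


class TestLevelProbabilities:
    def test_standard_normal_closed_form(self):
        from prefmap.estimators import FittedModel

        X = make_design({"x": np.zeros(1)}, intercept=False)
        model = FittedModel(
            family="oprobit", spec_id="", columns=("x",), coefficients={"x": 0.0},
            loglik=0.0, n_params=3, n_obs=1,
            extras={"cutpoints": [-1.0, 1.0], "n_categories": 3},
        )
        p = level_probabilities(model, X)[0]
        phi1 = stats.norm.cdf(1.0)
        np.testing.assert_allclose(p, [1 - phi1, 2 * phi1 - 1, 1 - phi1], atol=1e-12)

    def test_extreme_linear_index_concentrates_on_top_level(self):
        from prefmap.estimators import FittedModel

        X = make_design({"x": np.array([50.0])}, intercept=False)
        model = FittedModel(
            family="oprobit", spec_id="", columns=("x",), coefficients={"x": 1.0},
            loglik=0.0, n_params=3, n_obs=1,
            extras={"cutpoints": [-1.0, 1.0], "n_categories": 3},
        )
        p = level_probabilities(model, X)[0]
        assert p[-1] == pytest.approx(1.0, abs=1e-12)

    def test_rows_sum_to_one_and_match_cdf_differencing(self, cohort_small):
        model_set = fit_response_mapping(cohort_small, "M1", compute_se=False)
        X = build_design(cohort_small, "M1", intercept=False)
        for dim, model in model_set.models.items():
            p = level_probabilities(model, X)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
            cut = np.concatenate([[-np.inf], model.extras["cutpoints"], [np.inf]])
            eta = X.values @ model.beta
            oracle = stats.norm.cdf(cut[None, :] - eta[:, None])
            np.testing.assert_allclose(p, np.diff(oracle, axis=1), atol=1e-10)


class TestExpectedUtility:
    def test_point_mass_reduces_to_apply_tariff(self, tariff):
        from prefmap.instruments import Sf6dState, apply_tariff

        rng = np.random.default_rng(0)
        for _ in range(10):
            state = tuple(rng.integers(1, c + 1) for c in SF6D_LEVEL_COUNTS)
            probs = []
            for level, count in zip(state, SF6D_LEVEL_COUNTS):
                v = np.zeros(count)
                v[level - 1] = 1.0
                probs.append(v)
            eu = expected_utility(probs, tariff)[0]
            assert eu == pytest.approx(apply_tariff(Sf6dState(state), tariff), abs=1e-12)

    def test_enumeration_equals_additive_shortcut(self, tariff):
        rng = np.random.default_rng(1)
        probs = _random_prob_vectors(rng, n=5)
        add = expected_utility(probs, tariff, method="additive")
        enum = expected_utility(probs, tariff, method="enumerate")
        np.testing.assert_allclose(add, enum, atol=1e-12)

    def test_uniform_probabilities_closed_form(self, tariff):
        probs = [np.full(c, 1.0 / c) for c in SF6D_LEVEL_COUNTS]
        eu = expected_utility(probs, tariff)[0]
        expected = tariff.constant + sum(np.mean(d) for d in tariff.decrements)
        assert eu == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_floor_and_one(self, tariff):
        rng = np.random.default_rng(2)
        eu = expected_utility(_random_prob_vectors(rng, n=200), tariff)
        assert np.all(eu >= tariff.floor - 1e-12)
        assert np.all(eu <= 1.0 + 1e-12)

    def test_linear_in_each_probability_vector(self, tariff):
        rng = np.random.default_rng(3)
        p1 = _random_prob_vectors(rng)
        p2 = [v.copy() for v in p1]
        p2[2] = rng.dirichlet(np.ones(SF6D_LEVEL_COUNTS[2]), size=1)
        lam = 0.3
        mixed = [v.copy() for v in p1]
        mixed[2] = lam * p1[2] + (1 - lam) * p2[2]
        eu_mixed = expected_utility(mixed, tariff)[0]
        eu_lin = lam * expected_utility(p1, tariff)[0] + (1 - lam) * expected_utility(p2, tariff)[0]
        assert eu_mixed == pytest.approx(eu_lin, abs=1e-12)

    def test_length_mismatch_rejected(self, tariff):
        probs = [np.full(c, 1.0 / c) for c in SF6D_LEVEL_COUNTS]
        probs[0] = np.full(3, 1 / 3)
        with pytest.raises(ValueError, match="pf"):
            expected_utility(probs, tariff)


class TestFitResponseMapping:
    def test_combined_parameter_count_m5(self, cohort):
        model_set = fit_response_mapping(cohort, "M5", compute_se=False)
        # 12 slopes per dimension plus (J_d - 1) cutpoints, summed over the
        # six dimensions with full level occupancy: 72 + 25 = 97
        if all(
            m.extras["n_categories"] == c
            for m, c in zip(model_set.models.values(), SF6D_LEVEL_COUNTS)
        ):
            assert model_set.n_params == 97
        assert model_set.loglik == pytest.approx(
            sum(m.loglik for m in model_set.models.values())
        )

    def test_degenerate_dimension_collapses_with_warning(self, cohort_small):
        cohort = cohort_small.copy()
        # leave level 3 of role limitations unobserved
        cohort["sf6d_rl"] = cohort["sf6d_rl"].replace(3, 4)
        with pytest.warns(UserWarning, match="collapsed"):
            model_set = fit_response_mapping(cohort, "M1", compute_se=False)
        assert model_set.models["rl"].extras["level_map"] == {"1": 0, "2": 1, "4": 2}

    def test_mean_expected_utility_tracks_simulated_mean(self):
        """Consistency: at large n the fitted indirect mapping reproduces the
        cohort's mean utility."""
        cohort = generate_cohort(SimConfig(n=20_000, seed=21))
        model_set = fit_response_mapping(cohort, "M3", compute_se=False)
        from prefmap.instruments import default_tariff

        pred = predict_expected_utilities(model_set, cohort, default_tariff())
        assert pred.mean() == pytest.approx(cohort["utility"].mean(), abs=0.005)

    def test_serialization_round_trip(self, cohort_small, tariff, tmp_path):
        import json

        model_set = fit_response_mapping(cohort_small, "M1", compute_se=False)
        raw = json.dumps(model_set.to_dict())
        reloaded = ResponseModelSet.from_dict(json.loads(raw))
        a = predict_expected_utilities(model_set, cohort_small, tariff)
        b = predict_expected_utilities(reloaded, cohort_small, tariff)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestNonAdditiveTariff:
    def test_global_term_handled_by_enumeration(self):
        from prefmap.instruments import GlobalTerm, SF6D_LEVEL_COUNTS

        decs = []
        for count in SF6D_LEVEL_COUNTS:
            decs.append(tuple([0.0] + [-0.02 * j for j in range(1, count)]))
        term = GlobalTerm(min_levels={"pf": 4, "pain": 4}, value=-0.05)
        floor = 1.0 + sum(d[-1] for d in decs) - 0.05
        t = Tariff("nonadd", 1.0, tuple(decs), floor, (term,))
        rng = np.random.default_rng(4)
        probs = _random_prob_vectors(rng, n=3)
        eu = expected_utility(probs, t, method="enumerate")
        # the additive part plus the exact expectation of the global term
        add = expected_utility(probs, Tariff("add", 1.0, tuple(decs), floor + 0.05))
        p_term = probs[0][:, 3:].sum(axis=1) * probs[3][:, 3:].sum(axis=1)
        np.testing.assert_allclose(eu, add - 0.05 * p_term, atol=1e-12)

    def test_additive_shortcut_refused_with_global_terms(self, tariff):
        from prefmap.instruments import GlobalTerm

        t = Tariff(
            tariff.name, tariff.constant, tariff.decrements, tariff.floor,
            (GlobalTerm(min_levels={"pf": 5}, value=-0.01),),
        )
        probs = [np.full(c, 1.0 / c) for c in SF6D_LEVEL_COUNTS]
        with pytest.raises(ValueError, match="additive"):
            expected_utility(probs, t, method="additive")
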