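"""The five observation models: response probabilities, priors, joints."""

import math

import numpy as np
import pytest
from scipy import stats

import urnball as ub
from urnball.models import LAM_MIN, SIGMA_GAMMA_MAX, get_model


class TestResponseProbability:
    def test_ideal_observer_matches_posterior(self, conditions):
        q = ub.response_probability(
            "unweighted_bayes", conditions["PcLu"], ub.EvidenceSummary(3, 4)
        )
        assert round(q, 5) == 0.37692

    def test_base_rate_neglect_symmetric_sample(self):
        cond = ub.Condition("m", 0.1, 0.7, 0.3)
        q = ub.response_probability(
            "base_rate_neglect", cond, ub.EvidenceSummary(2, 4)
        )
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_base_rate_neglect_normalized_value(self, conditions):
        # 0.9^4 / (0.9^4 + 0.1^4), the flat-prior posterior
        q = ub.response_probability(
            "base_rate_neglect", conditions["PcLc"], ub.EvidenceSummary(4, 4)
        )
        assert round(q, 5) == 0.99985

    def test_base_rate_neglect_literal_reading(self, conditions):
        # the unnormalized sample likelihood P(E|H1) itself
        q = ub.response_probability(
            "base_rate_neglect_literal", conditions["PcLc"], ub.EvidenceSummary(4, 4)
        )
        assert q == pytest.approx(0.9**4, abs=1e-12)

    def test_unit_slope_weighting_equals_ideal_observer(self, conditions):
        w = ub.WeightingParams(1.0, 0.37)
        for cond in conditions.values():
            for k in range(5):
                ev = ub.EvidenceSummary(k, 4)
                assert ub.response_probability(
                    "weighted_pooled", cond, ev, w
                ) == pytest.approx(
                    ub.response_probability("unweighted_bayes", cond, ev),
                    abs=1e-12,
                )

    def test_missing_params_rejected(self, conditions):
        with pytest.raises(ValueError, match="requires weighting parameters"):
            ub.response_probability(
                "weighted_pooled", conditions["PcLc"], ub.EvidenceSummary(0, 4)
            )

    def test_probabilities_strictly_interior(self, conditions):
        # even extreme slopes cannot push the response probability to 0/1
        w = ub.WeightingParams(25.0, 0.5)
        for cond in conditions.values():
            for k in (0, 4):
                q = ub.response_probability(
                    "weighted_pooled", cond, ub.EvidenceSummary(k, 4), w
                )
                assert 0.0 < q < 1.0
                assert np.isfinite(math.log(q)) and np.isfinite(math.log(1 - q))


class TestPriorDensities:
    def test_gamma_prior_at_one(self):
        # half-normal-style normalizer: phi(0) / Phi(1)
        lp = ub.log_prior_density("weighted_pooled", (1.0, 0.5))
        assert math.exp(lp) == pytest.approx(0.47417, abs=5e-6)

    def test_flat_p0_prior_contributes_nothing(self):
        a = ub.log_prior_density("weighted_pooled", (1.0, 0.2))
        b = ub.log_prior_density("weighted_pooled", (1.0, 0.8))
        assert a == pytest.approx(b, abs=1e-12)

    def test_out_of_support_is_minus_inf(self):
        assert ub.log_prior_density("weighted_pooled", (-0.1, 0.5)) == -math.inf
        assert ub.log_prior_density("weighted_pooled", (1.0, 1.5)) == -math.inf

    def test_matches_scipy_truncnorm_oracle(self):
        for g in (0.2, 0.9, 2.3):
            lp = ub.log_prior_density("weighted_pooled", (g, 0.5))
            oracle = stats.truncnorm.logpdf(g, -1.0, np.inf, loc=1.0, scale=1.0)
            assert lp == pytest.approx(float(oracle), abs=1e-10)

    def test_parameter_free_has_no_prior(self):
        with pytest.raises(ValueError):
            ub.log_prior_density("unweighted_bayes", (1.0, 0.5))


class TestHyperPrior:
    def test_pareto_power_law_scaling(self):
        h1 = ub.HyperParams(1.0, 0.5, 0.5, 2.0)
        h2 = ub.HyperParams(1.0, 0.5, 0.5, 4.0)
        ratio = ub.log_hyperprior_density(h2) - ub.log_hyperprior_density(h1)
        assert math.exp(ratio) == pytest.approx(2.0**-2.5, rel=1e-10)

    def test_phi_is_flat(self):
        a = ub.log_hyperprior_density(ub.HyperParams(1.0, 0.5, 0.2, 2.0))
        b = ub.log_hyperprior_density(ub.HyperParams(1.0, 0.5, 0.7, 2.0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_support_edges(self):
        with pytest.raises(ValueError):
            ub.HyperParams(1.0, -0.5, 0.5, 2.0)
        with pytest.raises(ValueError):
            ub.HyperParams(1.0, 0.5, 0.5, LAM_MIN / 2)
        beyond = ub.HyperParams(1.0, SIGMA_GAMMA_MAX + 1, 0.5, 2.0)
        assert ub.log_hyperprior_density(beyond) == -math.inf


def _one_condition(fixture_data, label="PuLu"):
    trials, _ = fixture_data
    return trials[trials["condition"] == label]


class TestLogJoint:
    def test_zero_trials_is_prior_only(self, conditions):
        w = ub.WeightingParams(0.8, 0.3)
        lj = ub.log_joint("weighted_pooled", [], conditions["PcLc"], w)
        assert lj == pytest.approx(
            ub.log_prior_density("weighted_pooled", w), abs=1e-12
        )

    def test_parameter_free_closed_form(self, conditions, fixture_data):
        data = _one_condition(fixture_data)
        cond = conditions["PuLu"]
        lj = ub.log_joint("unweighted_bayes", data, cond)
        by_hand = 0.0
        for _, row in data.iterrows():
            q = ub.response_probability(
                "unweighted_bayes", cond, ub.EvidenceSummary(int(row["n_blue"]), 4)
            )
            by_hand += math.log(q) if row["response"] == 1 else math.log(1 - q)
        assert lj == pytest.approx(by_hand, rel=1e-12)

    def test_single_trial_unit_slope(self, conditions):
        cond = conditions["PcLu"]
        rec = [ub.TrialRecord("p1", "PcLu", 0, 3, 1)]
        w = ub.WeightingParams(1.0, 0.5)
        lj = ub.log_joint("weighted_pooled", rec, cond, w)
        expected = math.log(0.37692) + ub.log_prior_density("weighted_pooled", w)
        assert lj == pytest.approx(expected, abs=1e-4)

    def test_pointwise_sums_to_likelihood_part(self, conditions, fixture_data):
        data = _one_condition(fixture_data)
        cond = conditions["PuLu"]
        pids = sorted(data["participant_id"].unique())
        params = {p: ub.WeightingParams(0.6 + 0.02 * i, 0.3 + 0.02 * i)
                  for i, p in enumerate(pids)}
        hyper = ub.HyperParams(1.0, 0.5, 0.5, 5.0)
        pll = ub.pointwise_log_likelihood(
            "weighted_hierarchical", data, cond, params, hyper
        )
        assert len(pll) == len(data)
        prior_part = ub.log_joint(
            "weighted_hierarchical", [], cond, params, hyper
        )
        total = ub.log_joint("weighted_hierarchical", data, cond, params, hyper)
        assert pll.sum() + prior_part == pytest.approx(total, rel=1e-12)

    def test_hierarchical_prior_matches_scipy_oracle(self, conditions):
        params = {"a": ub.WeightingParams(0.7, 0.35),
                  "b": ub.WeightingParams(1.4, 0.6)}
        hyper = ub.HyperParams(0.9, 0.4, 0.55, 6.0)
        lj = ub.log_joint("weighted_hierarchical", [], conditions["PcLc"],
                          params, hyper)
        a = (0.0 - 0.9) / 0.4
        oracle = sum(
            stats.truncnorm.logpdf(w.gamma, a, np.inf, loc=0.9, scale=0.4)
            + stats.beta.logpdf(w.p0, hyper.alpha, hyper.beta)
            for w in params.values()
        ) + ub.log_hyperprior_density(hyper)
        assert lj == pytest.approx(float(oracle), rel=1e-10)

    def test_constant_probability_pointwise(self, conditions):
        # zero-slope weighting answers with p0 regardless of the evidence
        recs = [ub.TrialRecord("p1", "PcLc", i, i % 5, 1) for i in range(10)]
        w = ub.WeightingParams(0.0, 0.3)
        pll = ub.pointwise_log_likelihood("weighted_pooled", recs,
                                          conditions["PcLc"], w)
        assert np.allclose(pll, math.log(0.3), atol=1e-12)

    def test_unit_slope_pointwise_equals_ideal(self, conditions, fixture_data):
        data = _one_condition(fixture_data, "PcLc")
        cond = conditions["PcLc"]
        w = ub.WeightingParams(1.0, 0.5)
        a = ub.pointwise_log_likelihood("weighted_pooled", data, cond, w)
        b = ub.pointwise_log_likelihood("unweighted_bayes", data, cond)
        assert np.allclose(a, b, atol=1e-12)

    def test_participant_mismatch_rejected(self, conditions, fixture_data):
        data = _one_condition(fixture_data)
        params = {"nobody": ub.WeightingParams(1.0, 0.5)}
        with pytest.raises(ValueError, match="participants"):
            ub.log_joint("weighted_unrestricted", data, conditions["PuLu"], params)

    def test_hierarchical_requires_hyper(self, conditions, fixture_data):
        data = _one_condition(fixture_data)
        pids = sorted(data["participant_id"].unique())
        params = {p: ub.WeightingParams(1.0, 0.5) for p in pids}
        with pytest.raises(ValueError, match="HyperParams"):
            ub.log_joint("weighted_hierarchical", data, conditions["PuLu"], params)


class TestRegistry:
    def test_raw_parameter_counts(self):
        assert get_model("unweighted_bayes").n_parameters(16) == 0
        assert get_model("base_rate_neglect").n_parameters(16) == 0
        assert get_model("weighted_pooled").n_parameters(16) == 2
        assert get_model("weighted_unrestricted").n_parameters(16) == 32
        assert get_model("weighted_hierarchical").n_parameters(16) == 36

    def test_unknown_model(self):
        with pytest.raises(KeyError, match="registered models"):
            get_model("gradient_boosted_urns")
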