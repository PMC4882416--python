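"""lppd / WAIC / LOO-CV: hand oracles, invariants, and cross-checks."""

import math
import warnings

import numpy as np
import pytest

import urnball as ub
from urnball.evaluation import PointwiseLogLik, UnsupportedModelError


def toy_pll():
    """Two draws, one trial, likelihoods 0.2 and 0.4."""
    return PointwiseLogLik(np.log([[0.2], [0.4]]))


class TestLppd:
    def test_hand_oracle(self):
        assert ub.lppd(toy_pll()) == pytest.approx(math.log(0.3), abs=1e-12)

    def test_single_draw_degenerates_to_sum(self):
        vals = np.log(np.array([[0.3, 0.6, 0.9]]))
        assert ub.lppd(PointwiseLogLik(vals)) == pytest.approx(
            vals.sum(), abs=1e-12
        )

    def test_constant_matrix(self):
        pll = PointwiseLogLik(np.full((5, 7), -1.3))
        assert ub.lppd(pll) == pytest.approx(7 * -1.3, abs=1e-12)

    def test_logsumexp_equals_naive_on_benign_input(self):
        rng = np.random.default_rng(0)
        vals = np.log(rng.uniform(0.1, 0.9, size=(20, 15)))
        naive = np.log(np.exp(vals).mean(axis=0)).sum()
        assert ub.lppd(PointwiseLogLik(vals)) == pytest.approx(naive, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            PointwiseLogLik(np.empty((0, 0)))
        with pytest.raises(ValueError):
            PointwiseLogLik(np.array([[-np.inf]]))


class TestPWaic:
    def test_hand_oracle(self):
        assert ub.p_waic(toy_pll()) == pytest.approx(0.24023, abs=5e-6)

    def test_constant_columns_give_zero(self):
        pll = PointwiseLogLik(np.tile(np.log([0.2, 0.7, 0.5]), (6, 1)))
        assert ub.p_waic(pll) == 0.0

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            ub.p_waic(PointwiseLogLik(np.array([[-1.0]])))

    def test_invariant_to_reordering(self):
        rng = np.random.default_rng(3)
        vals = np.log(rng.uniform(0.05, 0.95, size=(30, 12)))
        base = ub.p_waic(PointwiseLogLik(vals))
        shuf_draws = vals[rng.permutation(30)]
        shuf_trials = vals[:, rng.permutation(12)]
        assert ub.p_waic(PointwiseLogLik(shuf_draws)) == pytest.approx(base)
        assert ub.p_waic(PointwiseLogLik(shuf_trials)) == pytest.approx(base)

    def test_constant_log_factor_leaves_p_waic_unchanged(self):
        rng = np.random.default_rng(4)
        vals = np.log(rng.uniform(0.05, 0.5, size=(30, 12)))
        assert ub.p_waic(PointwiseLogLik(vals + math.log(1.7))) == pytest.approx(
            ub.p_waic(PointwiseLogLik(vals))
        )


class TestWaic:
    def test_hand_oracle_deviance(self):
        score = ub.waic(toy_pll())
        assert score.lppd == pytest.approx(math.log(0.3), abs=1e-9)
        assert score.p_eff == pytest.approx(0.24023, abs=5e-6)
        assert score.deviance == pytest.approx(2.88840, abs=5e-6)

    def test_duplicating_trials_doubles_everything(self):
        rng = np.random.default_rng(5)
        vals = np.log(rng.uniform(0.1, 0.9, size=(25, 9)))
        one = ub.waic(PointwiseLogLik(vals))
        two = ub.waic(PointwiseLogLik(np.hstack([vals, vals])))
        assert two.lppd == pytest.approx(2 * one.lppd)
        assert two.p_eff == pytest.approx(2 * one.p_eff)
        assert two.deviance == pytest.approx(2 * one.deviance)

    def test_matches_arviz_cross_check(self):
        import arviz as az
        import xarray as xr

        rng = np.random.default_rng(6)
        # (chains, draws, trials) log-likelihoods
        ll = np.log(rng.uniform(0.1, 0.9, size=(2, 100, 14)))
        idata = az.from_dict(log_likelihood={"y": ll})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = az.waic(idata, scale="deviance")
        ours = ub.waic(PointwiseLogLik(ll.reshape(200, 14)))
        # arviz uses the population variance for p_waic; this package uses
        # the S-1 sample variance, an exact factor (S-1)/S per column
        s = 200
        p_eff_pop = ours.p_eff * (s - 1) / s
        dev_pop = -2.0 * (ours.lppd - p_eff_pop)
        assert dev_pop == pytest.approx(float(ref.elpd_waic), rel=1e-8)
        assert p_eff_pop == pytest.approx(float(ref.p_waic), rel=1e-8)


class TestParameterFreeScores:
    def test_waic_equals_loo_exactly(self, conditions, fixture_data):
        trials, _ = fixture_data
        data = trials[trials["condition"] == "PcLu"]
        for name in ("unweighted_bayes", "base_rate_neglect"):
            w = ub.score_parameter_free(name, data, conditions["PcLu"], "waic")
            l = ub.score_parameter_free(name, data, conditions["PcLu"], "loo")
            assert w.p_eff == 0.0 and l.p_eff == 0.0
            assert w.deviance == l.deviance  # exact, no tolerance
            pll = ub.pointwise_log_likelihood(name, data, conditions["PcLu"])
            assert w.deviance == pytest.approx(-2 * pll.sum(), rel=1e-12)

    def test_loo_dispatches_parameter_free(self, conditions, fixture_data):
        trials, _ = fixture_data
        data = trials[trials["condition"] == "PcLc"]
        cfg = ub.SamplerConfig.reduced(seed=0)
        score = ub.loo_participant_cv("unweighted_bayes", data,
                                      conditions["PcLc"], cfg)
        ref = ub.score_parameter_free("unweighted_bayes", data,
                                      conditions["PcLc"], "loo")
        assert score.deviance == ref.deviance

    def test_weighted_model_rejected(self, conditions, fixture_data):
        trials, _ = fixture_data
        with pytest.raises(ValueError):
            ub.score_parameter_free("weighted_pooled", trials, conditions["PcLc"])


class TestLooCV:
    def test_unrestricted_model_cannot_generalize(self, conditions,
                                                  fixture_data):
        trials, _ = fixture_data
        with pytest.raises(UnsupportedModelError, match="new participant"):
            ub.loo_participant_cv(
                "weighted_unrestricted", trials, conditions["PcLc"],
                ub.SamplerConfig.reduced(seed=0),
            )

    def test_symmetric_folds_give_equal_contributions(self, conditions):
        # two participants with identical trial sets: each fold trains on
        # the same data, so contributions agree up to Monte-Carlo error
        rows = []
        for pid in ("a", "b"):
            for t, (k, y) in enumerate([(0, 0), (1, 0), (2, 0), (3, 1),
                                        (4, 1)] * 6):
                rows.append({"participant_id": pid, "condition": "PuLu",
                             "trial_index": t, "n_blue": k, "response": y})
        import pandas as pd

        data = pd.DataFrame(rows)
        cfg = ub.SamplerConfig(chains=2, iterations=2000, warmup=1000, seed=4)
        score = ub.loo_participant_cv("weighted_pooled", data,
                                      conditions["PuLu"], cfg)
        assert score.deviance == pytest.approx(-2 * score.lppd, rel=1e-12)
        # the SE is sqrt(2 * Var) over the two fold contributions, which
        # differ only by Monte-Carlo error here, so it is tiny relative to
        # the total
        assert score.se < 0.02 * abs(score.deviance)

    def test_hierarchical_beats_pooled_on_heterogeneous_population(
        self, conditions
    ):
        # population with strong individual differences in both slope and
        # crossover; the hierarchical predictive should generalize to new
        # participants better than a single pooled weighting pair, on
        # average over replicates
        truth = ub.HyperParams(mu_gamma=1.0, sigma_gamma=0.8, phi=0.5, lam=1.2)
        cond = conditions["PuLu"]
        cfg = ub.SamplerConfig(chains=2, iterations=800, warmup=400, seed=0)
        diffs = []
        for rep in range(10):
            gen = ub.GeneratorConfig(
                n_participants=6, n_trials=60, conditions=(cond,),
                generative_model="weighted_hierarchical", true_params=truth,
                seed=100 + rep,
            )
            trials, _ = ub.generate_experiment(gen)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                hier = ub.loo_participant_cv(
                    "weighted_hierarchical", trials, cond, cfg,
                    n_predictive_draws=50, max_hyper_draws=100,
                )
                pooled = ub.loo_participant_cv(
                    "weighted_pooled", trials, cond, cfg
                )
            diffs.append(pooled.deviance - hier.deviance)
        assert np.mean(diffs) > 0

    def test_needs_two_participants(self, conditions):
        import pandas as pd

        data = pd.DataFrame(
            {"participant_id": ["a"] * 4, "condition": "PcLc",
             "trial_index": range(4), "n_blue": [0, 1, 2, 3],
             "response": [0, 0, 1, 1]}
        )
        with pytest.raises(ValueError, match="2 participants"):
            ub.loo_participant_cv("weighted_pooled", data, conditions["PcLc"],
                                  ub.SamplerConfig.reduced(seed=0))


class TestCompareReport:
    def test_report_layout_and_parameter_free_rows(self, conditions,
                                                   small_pooled_data):
        trials, _ = small_pooled_data
        cfg = ub.SamplerConfig(chains=2, iterations=600, warmup=300, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            report = ub.compare_models(
                trials, [conditions["PuLu"]],
                ["unweighted_bayes", "base_rate_neglect", "weighted_pooled"],
                cfg,
            )
        assert list(report.columns) == ["model", "condition", "lppd", "p_eff",
                                        "deviance", "se"]
        pf = report[report["model"].isin(["unweighted_bayes",
                                          "base_rate_neglect"])]
        assert (pf["p_eff"] == 0.0).all()
        assert (report["p_eff"] >= 0.0).all()
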