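"""Synthetic urn-ball experiments.

Emulates the factorial design of the behavioral study: four conditions
crossing a prior base rate P(H1) in {0.1, 0.3} with a blue-ball likelihood
P(blue|H1) in {0.9, 0.7} (urns mirrored), 16 participants, 50 trials per
condition, and a 4-ball sample drawn with replacement on every trial.  Each
trial draws an urn from the prior, a blue-ball count from the urn's
binomial, and a binary response from a chosen observation model.  For
hierarchical generation, each participant's weighting pair is drawn once
per condition from the group distributions and held fixed across that
participant's trials, mirroring the per-condition model fits.

True latent parameters are returned as a long-format "truth" table kept
separate from the trial data; fitting code never reads it — it exists only
for parameter-recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .models import HyperParams, ModelSpec, get_model, response_probability
from .task import Condition, EvidenceSummary, PAPER_CONDITIONS
from .weighting import WeightingParams

__all__ = [
    "GeneratorConfig",
    "DEFAULT_HYPERS",
    "simulate_trial",
    "generate_experiment",
    "paper_design_fixture",
]

#: Default group-level parameters for the shipped fixture: slopes centered
#: below 1 with moderate spread (inverse-S weighting with real individual
#: differences) and an uninformative-middle crossover population.
DEFAULT_HYPERS = HyperParams(mu_gamma=0.8, sigma_gamma=0.4, phi=0.5, lam=10.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Design and generative-model settings for one simulated experiment."""

    n_participants: int = 16
    n_trials: int = 50
    sample_size: int = 4
    conditions: tuple = tuple(PAPER_CONDITIONS.values())
    generative_model: str = "weighted_hierarchical"
    true_params: object = None  # WeightingParams | {pid: WP} | HyperParams
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials < 1 or self.sample_size < 1:
            raise ValueError("design sizes must be positive")
        model = get_model(self.generative_model)
        tp = self.true_params
        if model.parameter_free:
            if tp is not None:
                raise ValueError(f"{model.name} takes no true_params")
        elif model.hierarchical:
            if not isinstance(tp, HyperParams):
                raise ValueError("hierarchical generation needs HyperParams")
        elif model.individual:
            if not isinstance(tp, dict):
                raise ValueError("unrestricted generation needs a pid -> params map")
        else:
            if not isinstance(tp, WeightingParams):
                raise ValueError("pooled generation needs a WeightingParams")


def simulate_trial(
    cond: Condition,
    model: ModelSpec | str,
    params: WeightingParams | None,
    rng: np.random.Generator,
    sample_size: int = 4,
) -> dict:
    """One trial: hidden urn, binomial blue count, Bernoulli response.

    Returns a dict with keys ``urn`` (1 if the rare urn H1 was drawn),
    ``n_blue`` and ``response``.
    """
    urn_is_h1 = rng.random() < cond.prior_h1
    lik = cond.lik_blue_h1 if urn_is_h1 else cond.lik_blue_h2
    n_blue = int(rng.binomial(sample_size, lik))
    q = response_probability(model, cond, EvidenceSummary(n_blue, sample_size), params)
    response = int(rng.random() < q)
    return {"urn": int(urn_is_h1), "n_blue": n_blue, "response": response}


def _draw_individual(
    hyper: HyperParams, rng: np.random.Generator
) -> WeightingParams:
    """One (gamma, p0) pair from the group distributions."""
    if hyper.sigma_gamma <= 1e-12:
        gamma = max(hyper.mu_gamma, 0.0)
    else:
        a = (0.0 - hyper.mu_gamma) / hyper.sigma_gamma
        gamma = float(
            truncnorm.rvs(
                a, np.inf, loc=hyper.mu_gamma, scale=hyper.sigma_gamma,
                random_state=rng,
            )
        )
    p0 = float(np.clip(rng.beta(hyper.alpha, hyper.beta), 1e-9, 1 - 1e-9))
    return WeightingParams(gamma, p0)


def generate_experiment(config: GeneratorConfig):
    """Simulate a full factorial experiment.

    Returns ``(trials, truth)``: a trial table with columns
    ``participant_id, condition, trial_index, n_blue, response`` (one row
    per participant x condition x trial) and a long-format truth table
    (``condition, participant_id, parameter, value``) holding the latent
    parameters actually used, including hyper-parameter rows (with empty
    participant_id) for hierarchical generation.

    A single integer seed drives a splittable generator: every participant
    gets an independent child stream, so datasets are reproducible and
    participant-level streams do not interact.
    """
    model = get_model(config.generative_model)
    root = np.random.SeedSequence(config.seed)
    child_seeds = root.spawn(config.n_participants)
    participants = [f"p{i+1:02d}" for i in range(config.n_participants)]

    rows, truth_rows = [], []
    if model.hierarchical:
        for cond in config.conditions:
            for hp_name in ("mu_gamma", "sigma_gamma", "phi", "lam"):
                truth_rows.append(
                    {
                        "condition": cond.label,
                        "participant_id": "",
                        "parameter": hp_name,
                        "value": getattr(config.true_params, hp_name),
                    }
                )

    for pid, seed in zip(participants, child_seeds):
        rng = np.random.default_rng(seed)
        for cond in config.conditions:
            if model.parameter_free:
                w = None
            elif model.hierarchical:
                w = _draw_individual(config.true_params, rng)
            elif model.individual:
                w = config.true_params[pid]
            else:
                w = config.true_params
            if w is not None:
                truth_rows.append(
                    {
                        "condition": cond.label,
                        "participant_id": pid,
                        "parameter": "gamma",
                        "value": w.gamma,
                    }
                )
                truth_rows.append(
                    {
                        "condition": cond.label,
                        "participant_id": pid,
                        "parameter": "p0",
                        "value": w.p0,
                    }
                )
            for t in range(config.n_trials):
                rec = simulate_trial(cond, model, w, rng, config.sample_size)
                rows.append(
                    {
                        "participant_id": pid,
                        "condition": cond.label,
                        "trial_index": t,
                        "n_blue": rec["n_blue"],
                        "response": rec["response"],
                    }
                )

    trials = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def paper_design_fixture(seed: int = 0, hyper: HyperParams = DEFAULT_HYPERS):
    """The package's standard synthetic dataset.

    The full factorial design (16 participants x 4 conditions x 50 trials,
    4-ball samples) with responses generated by the hierarchical weighted
    model under :data:`DEFAULT_HYPERS`.  Returns ``(trials, truth)``.
    """
    config = GeneratorConfig(
        generative_model="weighted_hierarchical", true_params=hyper, seed=seed
    )
    return generate_experiment(config)
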