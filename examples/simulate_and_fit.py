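"""Simulate responses from a distorting observer and recover its parameters.

Generates one condition of the urn-ball experiment from the pooled weighted
model with a known slope and crossover, then samples the posterior of the
same model and prints the summary: the posterior means should sit near the
generating values.
"""

from urnball import (
    GeneratorConfig,
    PAPER_CONDITIONS,
    SamplerConfig,
    WeightingParams,
    generate_experiment,
    sample_posterior,
)

cond = PAPER_CONDITIONS["PuLu"]
truth = WeightingParams(gamma=0.6, p0=0.35)
gen = GeneratorConfig(
    n_participants=8,
    n_trials=150,
    conditions=(cond,),
    generative_model="weighted_pooled",
    true_params=truth,
    seed=21,
)
trials, _ = generate_experiment(gen)
print(f"simulated {len(trials)} trials in {cond.label} with "
      f"gamma={truth.gamma}, p0={truth.p0}")

fit = sample_posterior(
    "weighted_pooled", trials, cond, SamplerConfig.reduced(seed=3)
)
print(fit.summary().round(3).to_string(index=False))
print(
    "\nThe posterior means of gamma and p0 recover the generating values "
    "within their credible intervals; rhat near 1 indicates the chains "
    "mixed."
)
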