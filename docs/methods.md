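# Methods

## Task model and coding conventions

The task has two hidden states (urns): the *rare* urn H1 with prior
`P(H1) ∈ (0, 1)` and the common urn H2 with `P(H2) = 1 − P(H1)` (always
derived, never stored). A trial draws an urn from the prior and then `K`
balls i.i.d. with replacement, so the blue-ball count is a sufficient
statistic and draw order never enters any computation. The four standard
conditions are `PcLc = (0.1, 0.9/0.1)`, `PuLc = (0.3, 0.9/0.1)`,
`PcLu = (0.1, 0.7/0.3)`, `PuLu = (0.3, 0.7/0.3)` (prior of H1, blue
likelihood under H1/H2); custom conditions need not have mirrored urns.

Responses are coded package-wide as `1 = inference of the lower-prior
(rare) urn H1`, `0 = inference of the higher-prior urn`.

Natural logarithms are used throughout. Probabilities are clipped to
`[1e−12, 1 − 1e−12]` before log-odds are taken; the clip prevents infinite
log-likelihoods under extreme weighting slopes while being ten orders of
magnitude below the smallest probability arising in the 4-ball design, so
reference values are unaffected at any printed precision.

### A note on the published reference table

The reference table of ideal-observer posteriors contains one internally
inconsistent cell: for the uncertain-prior / certain-likelihood condition
with one blue ball of four, the printed probability (0.01526) does not
match the printed log-odds of the same cell (−5.24, which implies
0.00526). Since the log-odds row is consistent with Bayes' theorem (and
with the package's independent brute-force enumeration over all 2⁴ ordered
ball sequences), the probability cell is treated as a misprint; the
package computes and reports 0.00526.

## Probability weighting

Subjective probabilities are modeled as linear transformations in log-odds
space, `π = logistic(γ·Lo(p) + (1−γ)·Lo(p₀))`, with slope `γ ≥ 0` and
crossover `p₀` where `π(p₀) = p₀`. The crossover is restricted to the
*open* unit interval although the weak prior on it is `beta(1, 1)` on
`[0, 1]`: `Lo(p₀)` is undefined at the boundary, and the flat beta prior
puts zero mass there, so nothing is lost. `γ = 0` (constant response
probability `p₀`) is allowed; the formula is well defined and the
truncated-normal prior supports it. Because the transform is linear in
log-odds, weighting the posterior directly is algebraically identical to
multiplying the prior log-odds and every per-ball log likelihood ratio by
`γ` and adding the crossover offset once; tests verify the two routes agree
to 1e−10 on all design cells.

## Observation models and priors

All five models share the Bernoulli sampling statement for the response;
they differ in how the response probability is built and in parameter
structure:

- parameter-free: `unweighted_bayes` (exact posterior) and
  `base_rate_neglect` (flat-prior posterior).
- `weighted_pooled`: one `(γ, p₀)` pair; priors `γ ~ N(1, 1)` truncated to
  `[0, ∞)`, `p₀ ~ beta(1, 1)`.
- `weighted_unrestricted`: one pair per participant, each under the same
  weak priors independently.
- `weighted_hierarchical`: `γᵢ ~ N(μ_γ, σ_γ)[0, ∞)`,
  `p₀ᵢ ~ beta(φλ, (1−φ)λ)` with hyper-priors `μ_γ ~ N(1, 1)`,
  `σ_γ` flat positive, `φ ~ beta(1, 1)`, and `p(λ) ∝ λ^−2.5`.

The beta population over crossover points is parameterized by its mean
`φ = α/(α+β)` and total count `λ = α+β` rather than the raw shapes — the
mean/concentration parameterization standard for hierarchical beta models.

Two stated priors are improper and are replaced by proper, effectively
unrestrictive versions: `σ_γ ~ Uniform(0, 10)` (ten vastly exceeds any
plausible spread of slopes, whose own prior scale is 1) and
`λ ~ Pareto(λ_min = 0.1, shape 1.5)`, the proper power law with density
`∝ λ^−2.5`; a lower bound is mathematically required for the power law to
normalize, and 0.1 permits even extremely dispersed (bimodal) crossover
populations.

The base-rate-neglect sampling statement can be read two ways: as the
*normalized* flat-prior posterior `P(E|H1)/(P(E|H1)+P(E|H2))` or as the raw
sample likelihood `P(E|H1)` used directly as a Bernoulli rate. The
normalized reading is the only one consistent with the definition of the
bias (a genuinely flat prior applied in Bayes' rule) and is the default;
the literal reading is exposed as the registered model
`base_rate_neglect_literal` for comparison.

Models are fitted to each condition independently, so each condition gets
its own parameter set — matching how such data are typically analyzed and
keeping every fit low-dimensional (at most `2I + 4` parameters). Each
trial contributes one Bernoulli datum via the count-sufficient response
probability; the four individual ball draws within a trial are not modeled
as separate data. Likelihoods are evaluated from per-participant ×
blue-count response-count tables (sufficient statistics), which makes the
cost of a likelihood evaluation independent of the trial count.

## Sampler

Posteriors are drawn with a self-contained adaptive random-walk
Metropolis-within-Gibbs sampler. Bounded parameters are mapped to an
unconstrained scale (log for `γ` and `λ − λ_min`, log-odds for `p₀`, `φ`,
and `σ_γ/10`) with the Jacobian added to the target. Proposal scales are
adapted per coordinate toward a 0.44 acceptance rate with a Robbins–Monro
step `η_t = t^−0.6` **during warmup only** and frozen afterwards, so all
retained draws come from a fixed, detailed-balance-respecting kernel.
Chains are initialized from the priors (seeded, with a bounded number of
retries if the target is not finite at the draw).

For the individual-difference models the likelihood factorizes over
participants, so all `γᵢ` (and then all `p₀ᵢ`) are updated in one
vectorized block with elementwise accept/reject — statistically identical
to componentwise updates, an order of magnitude faster. The hierarchical
model additionally gets two joint moves per iteration that target the
location-scale funnel between `(μ_γ, σ_γ)` and the `γᵢ`: a *location* move
shifting `μ_γ` and every `γᵢ` by a common normal increment (symmetric
proposal, Jacobian 1) and a *scale* move rescaling `σ_γ` and the spread
`γᵢ − μ_γ` by a common log-normal factor `c` (involutive
Metropolis–Hastings with Jacobian `c^{I+1}`). Without these moves the
near-non-identified regime (saturated response probabilities under extreme
log-odds, as in the PcLc condition) mixes very slowly.

The default configuration mirrors the original analysis protocol (10
chains × 20,000 iterations, 10,000 warmup); tests and quick fits use the
reduced setting 4 × 2,000 / 1,000 (`SamplerConfig.reduced`). Identical
seed, data, and configuration give bit-identical draws. Convergence is
summarized by rank-normalized split R-hat and bulk ESS (computed with
ArviZ); any fit whose worst R-hat exceeds 1.01 is flagged with a warning
(and exit code 3 from the CLI). A Hamiltonian/NUTS backend is not bundled;
the generic `sample()` entry point (arbitrary log-posterior + per-coordinate
transforms) is the seam where one could be plugged in.

## Model evaluation

`lppd = Σₙ ln(S⁻¹ Σₛ p(yₙ|θˢ))` is computed via log-sum-exp.
`p_WAIC = Σₙ Var_s ln p(yₙ|θˢ)` uses the *sample* variance (denominator
S−1). WAIC is reported on the deviance scale `−2(lppd − p_WAIC)`, with the
conventional pointwise standard error `√(N·Var_n)` of the per-trial
deviance contributions. For the parameter-free models the likelihood is a
constant per trial, so `p_eff = 0` and WAIC equals `−2 Σ ln p(yₙ)` exactly.

Leave-one-participant-out CV refits the model to all but one participant
and scores the held-out trials pointwise under the predictive distribution
for a new individual; the score is `−2 Σᵢ lppdᵢ`. For the pooled model the
predictive uses the posterior draws of the shared pair; for the
hierarchical model each retained hyper-draw (thinned to at most 200 by
default) generates 100 fresh `(γ, p₀)` pairs from the population
distributions, and the held-out likelihood is averaged over all pairs. The
unrestricted model is refused with an explicit error: it specifies no
distribution over a new participant's parameters, so the procedure is
undefined for it. LOO standard errors are taken over *participant*
contributions (`√(I·Var_i)`) rather than trials, the natural unit when
whole participants are held out; parameter-free models again give
LOO = WAIC exactly.

The published score tables for the original behavioral data cannot be
reproduced because the raw per-trial responses are not publicly deposited;
the comparison report (`compare_models`, CLI `compare`) mirrors their
layout (model × condition, deviance + SE) and the pipeline's correctness
is established instead by hand-computed oracles, closed-form identities,
and simulation-based recovery and ranking checks.

## Synthetic data generator

The generator emulates the published design and is the package's study
condition: 16 participants, 4 conditions, 50 trials per condition, 4-ball
samples. Any registered observation model can generate responses; for
hierarchical generation each participant's `(γᵢ, p₀ᵢ)` is drawn once per
condition and held fixed across that condition's trials. The shipped
fixture (`paper_design_fixture`) uses `μ_γ = 0.8, σ_γ = 0.4, φ = 0.5,
λ = 10`: slopes centered below one with real spread (inverse-S weighting
with individual differences, the regime the model family was built for)
and a broad, centered crossover population. A single integer seed drives a
splittable generator (one independent child stream per participant), and
the true latent parameters are emitted as a separate long-format truth
table that fitting code never reads.

What the generator does *not* emulate: trial-to-trial dependence (real
participants may recall earlier responses to repeated samples; responses
here are conditionally i.i.d., exactly as the observation models assume),
response times, color/key counterbalancing, practice trials, and
task-order effects. Passing recovery tests therefore show that the
pipeline is *self-consistent* — it recovers the parameters of data
generated under its own assumptions — not that those assumptions hold for
any particular real dataset.

## Verification problem sizes

The test suite favors exact oracles (brute-force enumeration over ordered
ball sequences, conjugate closed forms, hand-computed WAIC cases) where
they exist, and sized-down simulations where sampling is required: the
conjugate check retains 20,000 draws; the headline recovery study uses the
full 16-participant design with 200 trials per condition at the reduced
sampler setting; model-selection ranking uses five replicates of the full
factorial fixture; the LOO ranking check uses ten replicates of a
6-participant, 60-trial single-condition population with strong individual
differences. These sizes give comfortable statistical margins for the
properties asserted while keeping the default suite in the minutes range.

## Known limitations

- Random-walk sampling needs many iterations per effective draw compared
  with gradient-based samplers; `λ` and `σ_γ` have the lowest ESS. The
  1.01 R-hat flag is deliberately strict; reduced-setting fits of the
  hierarchical model routinely trigger it and longer chains clear it.
- In conditions whose log-odds saturate the response probabilities
  (certain likelihoods), slopes above ~1 are only weakly identified and
  hierarchical posteriors for `μ_γ` are prior-influenced; this is a
  property of the design, not of the implementation.
- Hierarchical LOO integrates the new-participant predictive by plain
  Monte Carlo over hyper-draws; very diffuse hyper-posteriors would need
  more than the default 200 × 100 draws.
- Condition-level hyper-structure, mixture populations, and sequential
  (order) effects are out of scope.
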