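"""Model comparison: lppd, WAIC, and leave-one-participant-out CV.

The log pointwise predictive density of a fitted model is

.. math::

    \\mathrm{lppd} = \\sum_{n=1}^{N}
        \\ln\\Bigl(\\frac{1}{S}\\sum_{s=1}^{S} p(y_n\\,|\\,\\theta^s)\\Bigr),

computed with log-sum-exp for stability.  WAIC subtracts the effective
parameter count :math:`p_\\mathrm{WAIC} = \\sum_n \\mathrm{Var}_s
\\ln p(y_n|\\theta^s)` (sample variance, denominator :math:`S-1`) and is
reported on the deviance scale :math:`-2(\\mathrm{lppd} -
p_\\mathrm{WAIC})`, where smaller is better.

Leave-one-participant-out CV refits the model to all but one participant
and scores that participant's trials under the predictive distribution for
a *new* individual; the score is :math:`-2\\sum_i \\mathrm{lppd}_i`.  The
unrestricted individual-differences model is rejected here: it specifies no
distribution over parameters of an unseen individual, so it makes no
prediction to score.  Standard errors follow the usual pointwise
convention, over trials for WAIC and over participant contributions for
participant-level LOO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import truncnorm

from . import models as _m
from .sampler import PosteriorSamples, SamplerConfig, sample_posterior
from .task import Condition

__all__ = [
    "PointwiseLogLik",
    "ModelScore",
    "UnsupportedModelError",
    "lppd",
    "p_waic",
    "waic",
    "score_parameter_free",
    "pointwise_matrix",
    "waic_for",
    "loo_participant_cv",
    "compare_models",
]


class UnsupportedModelError(ValueError):
    """Raised when a model cannot be scored by the requested procedure."""


@dataclass
class PointwiseLogLik:
    """Matrix of per-draw, per-trial log-likelihoods (S draws x N trials)."""

    values: np.ndarray
    participant_index: np.ndarray | None = None  # (N,) trial -> participant

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("need a nonempty S x N matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-likelihood entries must be finite")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]


@dataclass
class ModelScore:
    """A deviance-scale score with its decomposition and standard error."""

    lppd: float
    p_eff: float
    deviance: float
    se: float
    criterion: str = "waic"  # or "loo"


def _pointwise_lppd(values: np.ndarray) -> np.ndarray:
    return logsumexp(values, axis=0) - np.log(values.shape[0])


def lppd(pll: PointwiseLogLik) -> float:
    """Log pointwise predictive density, summed over trials."""
    return float(_pointwise_lppd(pll.values).sum())


def p_waic(pll: PointwiseLogLik) -> float:
    """Effective number of parameters: summed posterior variances of log-lik."""
    if pll.n_draws < 2:
        raise ValueError("p_waic needs at least 2 posterior draws")
    return float(pll.values.var(axis=0, ddof=1).sum())


def waic(pll: PointwiseLogLik) -> ModelScore:
    """Deviance-scale WAIC with a pointwise (over-trials) standard error."""
    lp_n = _pointwise_lppd(pll.values)
    if pll.n_draws >= 2:
        pw_n = pll.values.var(axis=0, ddof=1)
    else:
        pw_n = np.zeros_like(lp_n)  # degenerate single-draw case
    dev_n = -2.0 * (lp_n - pw_n)
    n = dev_n.size
    se = float(np.sqrt(n * dev_n.var(ddof=1))) if n > 1 else 0.0
    return ModelScore(
        lppd=float(lp_n.sum()),
        p_eff=float(pw_n.sum()),
        deviance=float(dev_n.sum()),
        se=se,
        criterion="waic",
    )


# ---------------------------------------------------------------------------
# scores for registered models
# ---------------------------------------------------------------------------

def score_parameter_free(
    model, data, cond: Condition, criterion: str = "waic", sample_size: int = 4
) -> ModelScore:
    """Closed-form score of a parameter-free model: -2 sum ln p(y_n).

    WAIC and LOO coincide exactly here (p_eff = 0 and the prediction does
    not depend on the training fold).  The SE is over trials for WAIC and
    over participant totals for LOO.
    """
    model = _m.get_model(model) if isinstance(model, str) else model
    if not model.parameter_free:
        raise ValueError(f"{model.name!r} has free parameters; fit it instead")
    cd = _m._as_cond_data(data, cond, sample_size)
    ll_n = _m.pointwise_log_likelihood(model, cd, cond)
    dev = float(-2.0 * ll_n.sum())
    if criterion == "waic":
        dev_n = -2.0 * ll_n
        se = float(np.sqrt(dev_n.size * dev_n.var(ddof=1)))
    elif criterion == "loo":
        dev_i = np.array(
            [-2.0 * ll_n[cd.p_idx == i].sum() for i in range(cd.n_participants)]
        )
        se = (
            float(np.sqrt(dev_i.size * dev_i.var(ddof=1)))
            if dev_i.size > 1
            else 0.0
        )
    else:
        raise ValueError("criterion must be 'waic' or 'loo'")
    return ModelScore(lppd=dev / -2.0, p_eff=0.0, deviance=dev, se=se,
                      criterion=criterion)


def _draw_arrays(model, samples: PosteriorSamples, cd: _m.CondData):
    """Stack posterior draws into (S, I) gamma and p0 arrays."""
    if model.name == "weighted_pooled":
        g = samples.get("gamma")[:, None]
        p0 = samples.get("p0")[:, None]
        g = np.repeat(g, cd.n_participants, axis=1)
        p0 = np.repeat(p0, cd.n_participants, axis=1)
        return g, p0
    g = np.column_stack([samples.get(f"gamma[{p}]") for p in cd.participants])
    p0 = np.column_stack([samples.get(f"p0[{p}]") for p in cd.participants])
    return g, p0


def _pll_from_pairs(cd: _m.CondData, gamma: np.ndarray, p0: np.ndarray):
    """(S, N) log-lik matrix from (S, I) per-draw parameter arrays."""
    S, I = gamma.shape
    offset = (1.0 - gamma) * (np.log(p0) - np.log1p(-p0))
    logits = gamma[:, :, None] * cd.lo[None, None, :] + offset[:, :, None]
    prob = np.clip(_m.expit(logits), _m.CLIP, 1.0 - _m.CLIP)  # (S, I, K+1)
    q = prob[:, cd.p_idx, cd.k_idx]  # (S, N)
    return np.where(cd.y[None, :] == 1, np.log(q), np.log1p(-q))


def pointwise_matrix(
    model, samples: PosteriorSamples, data, cond: Condition, sample_size: int = 4
) -> PointwiseLogLik:
    """Per-draw, per-trial log-likelihoods of a fitted weighted model."""
    model = _m.get_model(model) if isinstance(model, str) else model
    if model.parameter_free:
        cd = _m._as_cond_data(data, cond, sample_size)
        ll = _m.pointwise_log_likelihood(model, cd, cond)
        return PointwiseLogLik(np.tile(ll, (2, 1)), cd.p_idx)
    cd = _m._as_cond_data(data, cond, sample_size)
    gamma, p0 = _draw_arrays(model, samples, cd)
    return PointwiseLogLik(_pll_from_pairs(cd, gamma, p0), cd.p_idx)


def waic_for(
    model,
    data,
    cond: Condition,
    config: SamplerConfig | None = None,
    samples: PosteriorSamples | None = None,
    sample_size: int = 4,
) -> ModelScore:
    """WAIC of any registered model, sampling first if needed."""
    model = _m.get_model(model) if isinstance(model, str) else model
    if model.parameter_free:
        return score_parameter_free(model, data, cond, "waic", sample_size)
    if samples is None:
        if config is None:
            raise ValueError("need a SamplerConfig or existing samples")
        samples = sample_posterior(model, data, cond, config, sample_size)
    return waic(pointwise_matrix(model, samples, data, cond, sample_size))


# ---------------------------------------------------------------------------
# leave-one-participant-out cross-validation
# ---------------------------------------------------------------------------

def _predictive_pairs_hierarchical(
    samples: PosteriorSamples,
    n_predictive_draws: int,
    max_hyper_draws: int,
    rng: np.random.Generator,
):
    """Sample new-individual (gamma, p0) pairs from retained hyper-draws."""
    mu = samples.get("mu_gamma")
    sig = samples.get("sigma_gamma")
    phi = samples.get("phi")
    lam = samples.get("lam")
    S = mu.size
    if S > max_hyper_draws:
        idx = np.linspace(0, S - 1, max_hyper_draws).astype(int)
        mu, sig, phi, lam = mu[idx], sig[idx], phi[idx], lam[idx]
    M = n_predictive_draws
    mu_r = np.repeat(mu, M)
    sig_r = np.repeat(sig, M)
    a = (0.0 - mu_r) / sig_r
    gamma = truncnorm.rvs(a, np.inf, loc=mu_r, scale=sig_r, random_state=rng)
    alpha = np.repeat(phi * lam, M)
    beta = np.repeat((1.0 - phi) * lam, M)
    p0 = rng.beta(alpha, beta)
    # beta draws can hit the boundary in floating point for tiny shapes
    p0 = np.clip(p0, _m.CLIP, 1.0 - _m.CLIP)
    return gamma, p0


def _heldout_lppd(cd_out: _m.CondData, gamma: np.ndarray, p0: np.ndarray):
    """Pointwise lppd of held-out trials under flat draws of (gamma, p0)."""
    pll = _pll_from_pairs(cd_out, gamma[:, None], p0[:, None])
    return _pointwise_lppd(pll)


def loo_participant_cv(
    model,
    data,
    cond: Condition,
    config: SamplerConfig,
    n_predictive_draws: int = 100,
    max_hyper_draws: int = 200,
    sample_size: int = 4,
) -> ModelScore:
    """Leave-one-participant-out CV score, -2 * sum of held-out lppd.

    Each fold refits the model to the remaining participants (fold seeds are
    derived from ``config.seed``).  For the hierarchical model the held-out
    participant's parameters are integrated over the population implied by
    each retained hyper-draw, using ``n_predictive_draws`` fresh (gamma, p0)
    pairs per (thinned) hyper-draw.  The SE is over participant
    contributions.
    """
    model = _m.get_model(model) if isinstance(model, str) else model
    if model.name == "weighted_unrestricted":
        raise UnsupportedModelError(
            "the unrestricted individual-differences model specifies no "
            "distribution for a new participant's parameters, so it cannot "
            "be cross-validated across participants"
        )
    if model.parameter_free:
        return score_parameter_free(model, data, cond, "loo", sample_size)

    cd = _m._as_cond_data(data, cond, sample_size)
    if cd.n_participants < 2:
        raise ValueError("LOO-CV needs at least 2 participants")
    frame = pd.DataFrame(
        {
            "participant_id": np.asarray(cd.participants, dtype=object)[cd.p_idx],
            "condition": cd.cond.label,
            "n_blue": cd.k_idx,
            "response": cd.y,
        }
    )
    fold_seeds = np.random.SeedSequence(config.seed).spawn(cd.n_participants)
    lppd_i = np.empty(cd.n_participants)
    for i, pid in enumerate(cd.participants):
        train = frame[frame["participant_id"] != pid]
        test = frame[frame["participant_id"] == pid]
        fold_cfg = SamplerConfig(
            chains=config.chains,
            iterations=config.iterations,
            warmup=config.warmup,
            seed=int(fold_seeds[i].generate_state(1)[0] % (2**31 - 1)),
            initial_scale=config.initial_scale,
            target_accept=config.target_accept,
        )
        fit = sample_posterior(model, train, cond, fold_cfg, sample_size)
        cd_out = _m.CondData.from_frame(test, cond, sample_size)
        if model.name == "weighted_pooled":
            gamma, p0 = fit.get("gamma"), fit.get("p0")
        else:
            rng = np.random.default_rng(fold_seeds[i])
            gamma, p0 = _predictive_pairs_hierarchical(
                fit, n_predictive_draws, max_hyper_draws, rng
            )
        lppd_i[i] = _heldout_lppd(cd_out, gamma, p0).sum()

    dev_i = -2.0 * lppd_i
    se = float(np.sqrt(dev_i.size * dev_i.var(ddof=1)))
    return ModelScore(
        lppd=float(lppd_i.sum()),
        p_eff=0.0,
        deviance=float(dev_i.sum()),
        se=se,
        criterion="loo",
    )


# ---------------------------------------------------------------------------
# comparison reports
# ---------------------------------------------------------------------------

def compare_models(
    data,
    conditions,
    model_names,
    config: SamplerConfig,
    sample_size: int = 4,
) -> pd.DataFrame:
    """WAIC comparison table: one row per model x condition.

    Columns: model, condition, lppd, p_eff, deviance, se.  Parameter-free
    models are scored in closed form; weighted models are sampled with a
    condition- and model-specific seed derived from ``config.seed``.
    """
    rows = []
    ss = np.random.SeedSequence(config.seed)
    for cond in conditions:
        for name in model_names:
            model = _m.get_model(name)
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            cfg = SamplerConfig(
                chains=config.chains,
                iterations=config.iterations,
                warmup=config.warmup,
                seed=sub_seed,
                initial_scale=config.initial_scale,
                target_accept=config.target_accept,
            )
            score = waic_for(model, data, cond, config=cfg,
                             sample_size=sample_size)
            rows.append(
                {
                    "model": name,
                    "condition": cond.label,
                    "lppd": score.lppd,
                    "p_eff": score.p_eff,
                    "deviance": score.deviance,
                    "se": score.se,
                }
            )
    return pd.DataFrame(rows)
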