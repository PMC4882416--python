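"""Posterior sampling via adaptive random-walk Metropolis-within-Gibbs.

Bounded parameters are mapped to an unconstrained scale (log for positive
quantities, log-odds for unit-interval ones) and sampled with componentwise
Gaussian random-walk proposals whose scales adapt toward a 0.44 acceptance
rate during warmup only, so detailed balance holds for all retained draws.
The models here are low-dimensional per condition (at most 2I + 4
parameters), where a well-adapted random walk mixes adequately.

The generic entry point :func:`sample` takes any log-posterior over a
constrained parameter vector plus one transform per coordinate; the
model-aware wrapper :func:`sample_posterior` builds the target for a
registered observation model from a trial table.  Convergence diagnostics
(rank-normalized split R-hat and effective sample size) are computed with
ArviZ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from . import models as _m
from .task import Condition
from .weighting import WeightingParams

__all__ = [
    "Transform",
    "Identity",
    "LogLower",
    "LogitInterval",
    "SamplerConfig",
    "PosteriorSamples",
    "sample",
    "sample_posterior",
    "rhat",
    "ess",
    "posterior_mean",
    "RHAT_WARN_THRESHOLD",
]

#: Fits with any parameter above this split-R-hat are flagged as unconverged.
RHAT_WARN_THRESHOLD = 1.01


# ---------------------------------------------------------------------------
# transforms between constrained and unconstrained scales
# ---------------------------------------------------------------------------

class Transform:
    """Bijection from an unconstrained real to a constrained parameter."""

    def constrain(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def unconstrain(self, theta: float) -> float:  # pragma: no cover
        raise NotImplementedError

    def log_jacobian(self, x: float) -> float:  # pragma: no cover
        """log |d constrain / dx| evaluated at unconstrained x."""
        raise NotImplementedError


class Identity(Transform):
    def constrain(self, x):
        return x

    def unconstrain(self, theta):
        return theta

    def log_jacobian(self, x):
        return 0.0


class LogLower(Transform):
    """theta = lower + exp(x): positives, optionally shifted."""

    def __init__(self, lower: float = 0.0):
        self.lower = lower

    def constrain(self, x):
        return self.lower + np.exp(x)

    def unconstrain(self, theta):
        if theta <= self.lower:
            raise ValueError(f"value {theta} not above lower bound {self.lower}")
        return np.log(theta - self.lower)

    def log_jacobian(self, x):
        return x


class LogitInterval(Transform):
    """theta = lower + width * logistic(x): bounded interval."""

    def __init__(self, lower: float = 0.0, upper: float = 1.0):
        self.lower = lower
        self.width = upper - lower

    def constrain(self, x):
        return self.lower + self.width * expit(x)

    def unconstrain(self, theta):
        u = (theta - self.lower) / self.width
        if not 0.0 < u < 1.0:
            raise ValueError(f"value {theta} outside interval")
        return logit(u)

    def log_jacobian(self, x):
        # log(width * sigma(x) * (1 - sigma(x)))
        s = expit(x)
        return np.log(self.width) + np.log(s) + np.log1p(-s)


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.

    Defaults mirror the study protocol (10 chains of 20,000 iterations with
    the first 10,000 discarded as warmup); :meth:`reduced` gives the smaller
    setting used for tests and quick fits (4 chains of 2,000 / 1,000).
    """

    chains: int = 10
    iterations: int = 20_000
    warmup: int = 10_000
    seed: int = 0
    initial_scale: float = 0.5
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 1:
            raise ValueError("chains and iterations must be positive")
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("warmup must satisfy 0 <= warmup < iterations")
        if self.initial_scale <= 0:
            raise ValueError("initial_scale must be positive")

    @property
    def n_retained(self) -> int:
        return self.chains * (self.iterations - self.warmup)

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "SamplerConfig":
        return cls(chains=4, iterations=2_000, warmup=1_000, seed=seed, **kw)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws on the constrained scale, with chain structure."""

    names: list
    draws: np.ndarray  # (chains, kept, dim)
    log_post: np.ndarray  # (chains, kept)
    config: SamplerConfig
    accept_rate: np.ndarray = field(default=None)  # (dim,) mean across chains

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def _index(self, parameter: str) -> int:
        try:
            return self.names.index(parameter)
        except ValueError:
            raise KeyError(
                f"unknown parameter {parameter!r}; available: {self.names}"
            ) from None

    def get(self, parameter: str) -> np.ndarray:
        """All retained draws of one parameter, flattened across chains."""
        return self.draws[:, :, self._index(parameter)].reshape(-1)

    def chain_draws(self, parameter: str) -> np.ndarray:
        """Draws of one parameter with shape (chains, kept)."""
        return self.draws[:, :, self._index(parameter)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: columns chain, draw, parameter, value."""
        c, k, d = self.draws.shape
        chain = np.repeat(np.arange(c), k * d)
        draw = np.tile(np.repeat(np.arange(k), d), c)
        param = np.tile(np.asarray(self.names, dtype=object), c * k)
        return pd.DataFrame(
            {
                "chain": chain,
                "draw": draw,
                "parameter": param,
                "value": self.draws.reshape(-1),
            }
        )

    def summary(self) -> pd.DataFrame:
        """Per-parameter mean, sd, quantiles, and convergence diagnostics."""
        rows = []
        for i, name in enumerate(self.names):
            x = self.draws[:, :, i]
            flat = x.reshape(-1)
            q5, q50, q95 = np.percentile(flat, [5, 50, 95])
            row = {
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q5": q5,
                "q50": q50,
                "q95": q95,
            }
            if self.draws.shape[0] >= 2:
                row["rhat"] = rhat(self, name)
                row["ess"] = ess(self, name)
            rows.append(row)
        return pd.DataFrame(rows)

    def max_rhat(self) -> float:
        return float(self.summary()["rhat"].max())


# ---------------------------------------------------------------------------
# core sampler
# ---------------------------------------------------------------------------

def _run_chain(log_post_unc, z0, dim, cfg: SamplerConfig, rng):
    """One adaptive componentwise random-walk chain; returns kept draws."""
    z = np.asarray(z0, dtype=float).copy()
    lp = log_post_unc(z)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite log posterior at initialization")
    kept = cfg.iterations - cfg.warmup
    out = np.empty((kept, dim))
    out_lp = np.empty(kept)
    log_scale = np.full(dim, np.log(cfg.initial_scale))
    n_acc = np.zeros(dim)

    # pre-draw innovations and uniforms in blocks for speed
    for it in range(cfg.iterations):
        eps = rng.standard_normal(dim)
        logu = np.log(rng.random(dim))
        for j in range(dim):
            zj_old = z[j]
            z[j] = zj_old + np.exp(log_scale[j]) * eps[j]
            lp_new = log_post_unc(z)
            dlp = lp_new - lp
            if logu[j] < dlp:
                lp = lp_new
                if it >= cfg.warmup:
                    n_acc[j] += 1
            else:
                z[j] = zj_old
            if it < cfg.warmup:
                # Robbins-Monro step toward the target acceptance rate
                alpha = min(1.0, np.exp(min(dlp, 0.0)))
                eta = (it + 1) ** -0.6
                log_scale[j] += eta * (alpha - cfg.target_accept)
        if it >= cfg.warmup:
            out[it - cfg.warmup] = z
            out_lp[it - cfg.warmup] = lp
    return out, out_lp, n_acc / max(kept, 1)


def sample(
    log_post,
    transforms,
    names,
    config: SamplerConfig,
    init=None,
    max_init_tries: int = 100,
) -> PosteriorSamples:
    """Sample an arbitrary target over a constrained parameter vector.

    Parameters
    ----------
    log_post
        Callable mapping a constrained parameter vector to an unnormalized
        log posterior (may return -inf outside the support).
    transforms
        One :class:`Transform` per coordinate; sampling happens on the
        unconstrained scale with the Jacobian correction applied.
    names
        Parameter names, same order as the vector.
    config
        Chains / iterations / warmup / seed.
    init
        Callable ``init(rng) -> constrained vector`` used per chain (e.g.
        prior draws); defaults to standard normals on the unconstrained
        scale.  Re-drawn up to ``max_init_tries`` times per chain if the
        target is not finite at the initial point.
    """
    dim = len(names)
    if len(transforms) != dim:
        raise ValueError("need one transform per parameter")

    def log_post_unc(z):
        theta = np.array([t.constrain(z[j]) for j, t in enumerate(transforms)])
        lp = log_post(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + sum(t.log_jacobian(z[j]) for j, t in enumerate(transforms))

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    all_draws, all_lp, all_acc = [], [], []
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        z0 = None
        for _ in range(max_init_tries):
            if init is None:
                cand = rng.standard_normal(dim)
            else:
                theta0 = np.asarray(init(rng), dtype=float)
                cand = np.array(
                    [t.unconstrain(theta0[j]) for j, t in enumerate(transforms)]
                )
            if np.isfinite(log_post_unc(cand)):
                z0 = cand
                break
        if z0 is None:
            raise RuntimeError(
                f"could not find a finite initialization in {max_init_tries} tries"
            )
        draws_u, lp, acc = _run_chain(log_post_unc, z0, dim, config, rng)
        draws_c = np.column_stack(
            [transforms[j].constrain(draws_u[:, j]) for j in range(dim)]
        )
        all_draws.append(draws_c)
        all_lp.append(lp)
        all_acc.append(acc)

    return PosteriorSamples(
        names=list(names),
        draws=np.stack(all_draws),
        log_post=np.stack(all_lp),
        config=config,
        accept_rate=np.mean(all_acc, axis=0),
    )


# ---------------------------------------------------------------------------
# model-aware sampling
# ---------------------------------------------------------------------------

def _build_target(model: _m.ModelSpec, cd: _m.CondData):
    """Names, transforms, vectorized log posterior, and prior initializer."""
    I = cd.n_participants
    if model.name == "weighted_pooled":
        names = ["gamma", "p0"]
        transforms = [LogLower(0.0), LogitInterval()]

        def log_post(theta):
            gamma, p0 = theta
            prob = _m._weighted_prob_matrix(cd.lo, gamma, p0)[0:1]
            ll = float(
                np.sum(cd.c1.sum(axis=0) * np.log(prob[0]))
                + np.sum(cd.c0.sum(axis=0) * np.log1p(-prob[0]))
            )
            lp = float(_m._log_truncnorm(gamma, 1.0, 1.0) + _m._log_beta(p0, 1, 1))
            return ll + lp

        def init(rng):
            g = truncnorm.rvs(-1.0, np.inf, loc=1.0, scale=1.0, random_state=rng)
            return np.array([g, rng.uniform(0.02, 0.98)])

        return names, transforms, log_post, init

    pids = cd.participants
    names = [f"gamma[{p}]" for p in pids] + [f"p0[{p}]" for p in pids]
    transforms = [LogLower(0.0)] * I + [LogitInterval()] * I

    if model.name == "weighted_unrestricted":

        def log_post(theta):
            gamma, p0 = theta[:I], theta[I : 2 * I]
            prob = _m._weighted_prob_matrix(cd.lo, gamma, p0)
            ll = cd.loglik_from_matrix(prob)
            lp = float(np.sum(_m._log_truncnorm(gamma, 1.0, 1.0)))
            lp += float(np.sum(_m._log_beta(p0, 1.0, 1.0)))
            return ll + lp

        def init(rng):
            g = truncnorm.rvs(
                -1.0, np.inf, loc=1.0, scale=1.0, size=I, random_state=rng
            )
            return np.concatenate([g, rng.uniform(0.02, 0.98, size=I)])

        return names, transforms, log_post, init

    if model.name == "weighted_hierarchical":
        names = names + ["mu_gamma", "sigma_gamma", "phi", "lam"]
        transforms = transforms + [
            Identity(),
            LogitInterval(0.0, _m.SIGMA_GAMMA_MAX),
            LogitInterval(),
            LogLower(_m.LAM_MIN),
        ]

        def log_post(theta):
            gamma, p0 = theta[:I], theta[I : 2 * I]
            mu_g, sig_g, phi, lam = theta[2 * I :]
            prob = _m._weighted_prob_matrix(cd.lo, gamma, p0)
            ll = cd.loglik_from_matrix(prob)
            lp = float(np.sum(_m._log_truncnorm(gamma, mu_g, sig_g)))
            a, b = phi * lam, (1.0 - phi) * lam
            lp += float(np.sum(_m._log_beta(p0, a, b)))
            try:
                h = _m.HyperParams(mu_g, sig_g, phi, lam)
            except ValueError:
                return -np.inf
            return ll + lp + _m.log_hyperprior_density(h)

        def init(rng):
            mu_g = rng.normal(1.0, 1.0)
            sig_g = rng.uniform(0.05, 2.0)
            phi = rng.uniform(0.05, 0.95)
            lam = _m.LAM_MIN * (1.0 - rng.random()) ** (-1.0 / _m.PARETO_SHAPE)
            lam = min(lam, 1e3)
            a = max(mu_g, 0.0)
            g = truncnorm.rvs(
                (0.0 - a) / sig_g, np.inf, loc=a, scale=sig_g, size=I,
                random_state=rng,
            )
            p0 = rng.uniform(0.05, 0.95, size=I)
            return np.concatenate([g, p0, [mu_g, sig_g, phi, lam]])

        return names, transforms, log_post, init

    raise ValueError(f"model {model.name!r} is not a sampleable weighted model")


# ---------------------------------------------------------------------------
# fast path for individual-difference models
#
# The Bernoulli likelihood factorizes over participants and, given the
# hyper-parameters, so do the individual priors.  All gamma_i (then all
# p0_i) can therefore be updated in one vectorized Metropolis step with
# elementwise accept/reject; only the four hyper-parameters need scalar
# updates.  Statistically this is the same componentwise random-walk scheme
# as the generic path, just evaluated in parallel blocks.
# ---------------------------------------------------------------------------

def _logit_jac(z):
    """log derivative of the logistic transform, stable at saturation."""
    return -(np.logaddexp(0.0, z) + np.logaddexp(0.0, -z))


def _individual_loglik(cd: _m.CondData, gamma: np.ndarray, p0: np.ndarray):
    """Per-participant Bernoulli log-likelihood vector (I,)."""
    prob = _m._weighted_prob_matrix(cd.lo, gamma, p0)
    return (cd.c1 * np.log(prob)).sum(axis=1) + (
        cd.c0 * np.log1p(-prob)
    ).sum(axis=1)


def _run_chain_blocked(model, cd, cfg: SamplerConfig, rng, theta0):
    """One chain for weighted_unrestricted / weighted_hierarchical."""
    I = cd.n_participants
    hier = model.hierarchical
    zg = np.log(np.maximum(theta0[:I], 1e-10))
    zp = np.log(theta0[I : 2 * I]) - np.log1p(-theta0[I : 2 * I])
    gamma, p0 = np.exp(zg), expit(zp)
    if hier:
        mu_g, sig_g, phi, lam = theta0[2 * I :]
    else:
        mu_g, sig_g, phi, lam = 1.0, 1.0, None, None
        a_b = (1.0, 1.0)

    def ind_prior(g, p):
        if hier:
            a, b = phi * lam, (1.0 - phi) * lam
        else:
            a, b = a_b
        return _m._log_truncnorm(g, mu_g, sig_g) + _m._log_beta(p, a, b)

    def hyper_target(mu, sig, ph, lm):
        if not (0.0 < sig < _m.SIGMA_GAMMA_MAX) or lm < _m.LAM_MIN:
            return -np.inf
        if not (0.0 < ph < 1.0):
            return -np.inf
        val = float(np.sum(_m._log_truncnorm(gamma, mu, sig)))
        val += float(np.sum(_m._log_beta(p0, ph * lm, (1.0 - ph) * lm)))
        return val + _m.log_hyperprior_density(_m.HyperParams(mu, sig, ph, lm))

    ll = _individual_loglik(cd, gamma, p0)
    lpr = ind_prior(gamma, p0)

    # adaptive scales: one per individual coordinate, one per hyper
    sg = np.full(I, np.log(cfg.initial_scale))
    sp = np.full(I, np.log(cfg.initial_scale))
    kept = cfg.iterations - cfg.warmup
    if hier:
        # unconstrained hyper state and transforms (same as generic path)
        h_tr = [
            Identity(),
            LogitInterval(0.0, _m.SIGMA_GAMMA_MAX),
            LogitInterval(),
            LogLower(_m.LAM_MIN),
        ]
        zh = np.array(
            [h_tr[j].unconstrain(v) for j, v in enumerate([mu_g, sig_g, phi, lam])]
        )
        sh = np.full(4, np.log(cfg.initial_scale))
        s_loc = s_scl = np.log(cfg.initial_scale)
        lph = hyper_target(mu_g, sig_g, phi, lam) + sum(
            h_tr[j].log_jacobian(zh[j]) for j in range(4)
        )
        out = np.empty((kept, 2 * I + 4))
    else:
        out = np.empty((kept, 2 * I))
    out_lp = np.empty(kept)

    for it in range(cfg.iterations):
        eta = (it + 1) ** -0.6 if it < cfg.warmup else 0.0

        # --- block update of all gamma_i ---
        zg_new = zg + np.exp(sg) * rng.standard_normal(I)
        g_new = np.exp(zg_new)
        ll_new = _individual_loglik(cd, g_new, p0)
        lpr_new = ind_prior(g_new, p0)
        dlp = (ll_new - ll) + (lpr_new - lpr) + (zg_new - zg)
        acc = np.log(rng.random(I)) < dlp
        zg, gamma = np.where(acc, zg_new, zg), np.where(acc, g_new, gamma)
        ll, lpr = np.where(acc, ll_new, ll), np.where(acc, lpr_new, lpr)
        if eta:
            sg += eta * (np.exp(np.minimum(dlp, 0.0)) - cfg.target_accept)

        # --- block update of all p0_i ---
        zp_new = zp + np.exp(sp) * rng.standard_normal(I)
        p_new = expit(zp_new)
        ll_new = _individual_loglik(cd, gamma, p_new)
        lpr_new = ind_prior(gamma, p_new)
        # log|d expit/dz| = -softplus(z) - softplus(-z), stable at saturation
        jac = _logit_jac(zp_new) - _logit_jac(zp)
        dlp = (ll_new - ll) + (lpr_new - lpr) + jac
        acc = np.log(rng.random(I)) < dlp
        zp, p0 = np.where(acc, zp_new, zp), np.where(acc, p_new, p0)
        ll, lpr = np.where(acc, ll_new, ll), np.where(acc, lpr_new, lpr)
        if eta:
            sp += eta * (np.exp(np.minimum(dlp, 0.0)) - cfg.target_accept)

        # --- joint funnel moves for the gamma hierarchy ---
        # Componentwise updates mix poorly when sigma_gamma is small: the
        # gamma_i and mu_gamma are then almost perfectly coupled.  Two
        # joint Metropolis moves break that coupling: a location move
        # (shift mu_gamma and every gamma_i by the same delta, Jacobian 1)
        # and a scale move (rescale sigma_gamma and the gamma_i spread by
        # a common factor c; involutive-MH Jacobian c^(I+1)).
        if hier:
            delta = np.exp(s_loc) * rng.standard_normal()
            g_new, mu_new = gamma + delta, mu_g + delta
            if np.all(g_new > 0.0):
                ll_new = _individual_loglik(cd, g_new, p0)
                lpr_new = _m._log_truncnorm(g_new, mu_new, sig_g) + _m._log_beta(
                    p0, phi * lam, (1.0 - phi) * lam
                )
                d = float(
                    (ll_new - ll).sum()
                    + (lpr_new - lpr).sum()
                    - 0.5 * ((mu_new - 1.0) ** 2 - (mu_g - 1.0) ** 2)
                )
            else:
                d = -np.inf
            if np.log(rng.random()) < d:
                gamma, mu_g, ll, lpr = g_new, mu_new, ll_new, lpr_new
                zg = np.log(gamma)
                zh[0] = mu_g
            if eta:
                s_loc += eta * (np.exp(min(d, 0.0)) - cfg.target_accept)

            u = np.exp(s_scl) * rng.standard_normal()
            c = np.exp(u)
            sig_new = c * sig_g
            g_new = mu_g + c * (gamma - mu_g)
            if np.all(g_new > 0.0) and 0.0 < sig_new < _m.SIGMA_GAMMA_MAX:
                ll_new = _individual_loglik(cd, g_new, p0)
                lpr_new = _m._log_truncnorm(g_new, mu_g, sig_new) + _m._log_beta(
                    p0, phi * lam, (1.0 - phi) * lam
                )
                d = float(
                    (ll_new - ll).sum()
                    + (lpr_new - lpr).sum()
                    + (I + 1) * u
                )
            else:
                d = -np.inf
            if np.log(rng.random()) < d:
                gamma, sig_g, ll, lpr = g_new, sig_new, ll_new, lpr_new
                zg = np.log(gamma)
                zh[1] = h_tr[1].unconstrain(sig_g)
            if eta:
                s_scl += eta * (np.exp(min(d, 0.0)) - cfg.target_accept)

        # --- scalar updates of the hyper-parameters ---
        if hier:
            # the cached hyper target depends on gamma/p0, which the block
            # updates above may have moved: refresh it before the sweep
            lph = hyper_target(mu_g, sig_g, phi, lam) + sum(
                h_tr[m].log_jacobian(zh[m]) for m in range(4)
            )
            for j in range(4):
                zh_new = zh.copy()
                zh_new[j] += np.exp(sh[j]) * rng.standard_normal()
                hvals = [h_tr[m].constrain(zh_new[m]) for m in range(4)]
                lt = hyper_target(*hvals)
                lp_new = (
                    lt + sum(h_tr[m].log_jacobian(zh_new[m]) for m in range(4))
                    if np.isfinite(lt)
                    else -np.inf
                )
                d = lp_new - lph
                if np.log(rng.random()) < d:
                    zh, lph = zh_new, lp_new
                    mu_g, sig_g, phi, lam = hvals
                    lpr = ind_prior(gamma, p0)  # hyper move shifts ind priors
                if eta:
                    sh[j] += eta * (np.exp(min(d, 0.0)) - cfg.target_accept)

        if it >= cfg.warmup:
            k = it - cfg.warmup
            if hier:
                out[k] = np.concatenate([gamma, p0, [mu_g, sig_g, phi, lam]])
                out_lp[k] = float(ll.sum() + lpr.sum()) + _m.log_hyperprior_density(
                    _m.HyperParams(mu_g, sig_g, phi, lam)
                )
            else:
                out[k] = np.concatenate([gamma, p0])
                out_lp[k] = float(ll.sum() + lpr.sum())
    return out, out_lp


def _sample_individual(model, cd, config: SamplerConfig) -> PosteriorSamples:
    names, _transforms, log_post, init = _build_target(model, cd)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    all_draws, all_lp = [], []
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        theta0 = None
        for _ in range(100):
            cand = np.asarray(init(rng), dtype=float)
            if np.isfinite(log_post(cand)):
                theta0 = cand
                break
        if theta0 is None:
            raise RuntimeError("could not find a finite initialization")
        draws, lp = _run_chain_blocked(model, cd, config, rng, theta0)
        all_draws.append(draws)
        all_lp.append(lp)
    return PosteriorSamples(
        names=list(names),
        draws=np.stack(all_draws),
        log_post=np.stack(all_lp),
        config=config,
    )


def sample_posterior(
    model,
    data,
    cond: Condition,
    config: SamplerConfig,
    sample_size: int = 4,
) -> PosteriorSamples:
    """Draw posterior samples for a registered weighted model.

    Raises for the parameter-free models, whose predictive quantities have
    closed forms and need no sampling (see :mod:`urnball.evaluation`).
    Identical data, condition, and config (including seed) give bit-identical
    draws.
    """
    model = _m.get_model(model) if isinstance(model, str) else model
    if model.parameter_free:
        raise ValueError(
            f"model {model.name!r} has no free parameters; evaluate it in "
            "closed form (evaluation.score_parameter_free) instead of sampling"
        )
    cd = _m._as_cond_data(data, cond, sample_size)
    if cd.n_trials == 0:
        raise ValueError("data must contain at least one trial")
    if model.individual:
        samples = _sample_individual(model, cd, config)
    else:
        names, transforms, log_post, init = _build_target(model, cd)
        samples = sample(log_post, transforms, names, config, init=init)
    if config.chains >= 2:
        worst = samples.max_rhat()
        if worst > RHAT_WARN_THRESHOLD:
            warnings.warn(
                f"fit of {model.name} on {cond.label}: max R-hat {worst:.3f} "
                f"exceeds {RHAT_WARN_THRESHOLD}; treat estimates with caution",
                RuntimeWarning,
                stacklevel=2,
            )
    return samples


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _az():
    import arviz

    return arviz


def rhat(samples: PosteriorSamples, parameter: str) -> float:
    """Rank-normalized split potential-scale-reduction factor."""
    x = samples.chain_draws(parameter)
    if x.shape[0] < 2:
        raise ValueError("rhat requires at least 2 chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(_az().rhat(x))


def ess(samples: PosteriorSamples, parameter: str) -> float:
    """Bulk effective sample size of one parameter."""
    x = samples.chain_draws(parameter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(_az().ess(x))


def posterior_mean(samples: PosteriorSamples, parameter: str) -> float:
    """Arithmetic mean of retained draws on the constrained scale."""
    return float(samples.get(parameter).mean())


def individual_params_from_means(
    samples: PosteriorSamples, participants
) -> dict:
    """Posterior-mean weighting pairs per participant (for curve exports)."""
    return {
        p: WeightingParams(
            posterior_mean(samples, f"gamma[{p}]"),
            posterior_mean(samples, f"p0[{p}]"),
        )
        for p in participants
    }
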