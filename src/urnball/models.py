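"""Observation models of urn inference.

Five Bernoulli response models map a trial's evidence (blue-ball count) to
the probability of inferring the rare urn :math:`H_1` (response coding:
1 = lower-prior urn :math:`H_1`, 0 = higher-prior urn):

``unweighted_bayes``
    Probability matching on the exact posterior, ``y ~ bern(P(H1|E))``.
    Parameter-free.
``base_rate_neglect``
    The prior is ignored (treated as flat); the response probability is the
    normalized likelihood ``P(E|H1) / (P(E|H1) + P(E|H2))``.  Parameter-free.
    A ``literal`` switch exposes the raw, unnormalized sample likelihood
    ``P(E|H1)`` as the Bernoulli parameter instead (an alternative reading
    of the model statement; the normalized form is the default because it is
    the only one consistent with a genuinely flat prior).
``weighted_pooled``
    One (gamma, p0) weighting pair shared by all participants; responses are
    matched to the *subjective* (log-odds-weighted) posterior.
``weighted_unrestricted``
    An independent (gamma_i, p0_i) pair per participant, each under the weak
    priors gamma ~ N(1,1) truncated at 0 and p0 ~ beta(1,1).
``weighted_hierarchical``
    Per-participant pairs drawn from group-level distributions
    gamma_i ~ N(mu_gamma, sigma_gamma)[0, inf) and p0_i ~ beta(phi*lam,
    (1-phi)*lam), with weakly informative hyper-priors.

All models share the Bernoulli sampling statement for the data; they differ
only in how the response probability is built and in the prior structure.
Trials are exchangeable given (participant, n_blue), so likelihoods are
evaluated from sufficient-statistic count tables for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, log_ndtr
from scipy.stats import norm

from .task import CLIP, Condition, EvidenceSummary, log_odds, posterior_log_odds
from .weighting import WeightingParams

__all__ = [
    "MODEL_NAMES",
    "PARAMETER_FREE_MODELS",
    "WEIGHTED_MODELS",
    "ModelSpec",
    "HyperParams",
    "TrialRecord",
    "get_model",
    "response_probability",
    "log_prior_density",
    "log_hyperprior_density",
    "log_joint",
    "pointwise_log_likelihood",
    "SIGMA_GAMMA_MAX",
    "LAM_MIN",
]

#: Upper bound standing in for the improper Uniform(0, inf) prior on
#: sigma_gamma; far above any plausible spread of individual slopes.
SIGMA_GAMMA_MAX = 10.0
#: Lower bound of the power-law prior p(lam) ∝ lam^-2.5 on the beta total
#: count (a proper Pareto needs one); 0.1 is effectively unrestrictive.
LAM_MIN = 0.1
#: Pareto shape such that the density is ∝ lam^-(shape+1) = lam^-2.5.
PARETO_SHAPE = 1.5

MODEL_NAMES = (
    "unweighted_bayes",
    "base_rate_neglect",
    "weighted_pooled",
    "weighted_unrestricted",
    "weighted_hierarchical",
)
PARAMETER_FREE_MODELS = ("unweighted_bayes", "base_rate_neglect")
WEIGHTED_MODELS = (
    "weighted_pooled",
    "weighted_unrestricted",
    "weighted_hierarchical",
)


@dataclass(frozen=True)
class ModelSpec:
    """A registered observation model.

    ``parameter_free`` models have closed-form likelihoods; ``individual``
    models carry one weighting pair per participant; the hierarchical model
    additionally carries four group-level hyper-parameters.
    """

    name: str
    parameter_free: bool
    individual: bool
    hierarchical: bool
    literal_likelihood: bool = False  # base-rate-neglect variant switch

    def n_parameters(self, n_participants: int) -> int:
        """Raw free-parameter count for one condition."""
        if self.parameter_free:
            return 0
        if self.hierarchical:
            return 2 * n_participants + 4
        if self.individual:
            return 2 * n_participants
        return 2


_REGISTRY: dict[str, ModelSpec] = {
    "unweighted_bayes": ModelSpec("unweighted_bayes", True, False, False),
    "base_rate_neglect": ModelSpec("base_rate_neglect", True, False, False),
    "base_rate_neglect_literal": ModelSpec(
        "base_rate_neglect_literal", True, False, False, literal_likelihood=True
    ),
    "weighted_pooled": ModelSpec("weighted_pooled", False, False, False),
    "weighted_unrestricted": ModelSpec("weighted_unrestricted", False, True, False),
    "weighted_hierarchical": ModelSpec("weighted_hierarchical", False, True, True),
}


def get_model(name: str) -> ModelSpec:
    """Look up a model by name; raises ``KeyError`` with the known names."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered models: {sorted(_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class HyperParams:
    """Group-level parameters of the hierarchical model.

    ``mu_gamma``/``sigma_gamma`` locate and spread the truncated-normal
    population of slopes; the beta population of crossover points is
    parameterised by its mean ``phi`` and total count ``lam`` (shape
    parameters alpha = phi*lam, beta = (1-phi)*lam).
    """

    mu_gamma: float
    sigma_gamma: float
    phi: float
    lam: float

    def __post_init__(self) -> None:
        if not self.sigma_gamma > 0:
            raise ValueError("sigma_gamma must be > 0")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie strictly in (0, 1)")
        if not self.lam >= LAM_MIN:
            raise ValueError(f"lam must be >= {LAM_MIN}")

    @property
    def alpha(self) -> float:
        return self.phi * self.lam

    @property
    def beta(self) -> float:
        return (1.0 - self.phi) * self.lam


@dataclass(frozen=True)
class TrialRecord:
    """One participant's binary urn inference for one 4-ball sample."""

    participant: str
    condition: str
    trial_index: int
    n_blue: int
    response: int

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValueError("response must be 0 or 1")
        if self.n_blue < 0:
            raise ValueError("n_blue must be >= 0")


# ---------------------------------------------------------------------------
# response probabilities
# ---------------------------------------------------------------------------

def _clip(p):
    return np.clip(p, CLIP, 1.0 - CLIP)


def _posterior_lo_vector(cond: Condition, sample_size: int) -> np.ndarray:
    """Exact posterior log-odds for every blue count 0..K."""
    return np.array(
        [
            posterior_log_odds(cond, EvidenceSummary(k, sample_size))
            for k in range(sample_size + 1)
        ]
    )


def _base_probability(
    model: ModelSpec, cond: Condition, sample_size: int
) -> np.ndarray:
    """Model-specific objective response probability per blue count.

    For the weighted models this is the exact posterior, to which the
    weighting is then applied; for base-rate neglect the prior term is
    dropped before normalization.
    """
    lo = _posterior_lo_vector(cond, sample_size)
    if model.name.startswith("base_rate_neglect"):
        prior_lo = np.log(cond.prior_h1) - np.log(cond.prior_h2)
        if model.literal_likelihood:
            k = np.arange(sample_size + 1)
            return _clip(
                cond.lik_blue_h1**k * (1.0 - cond.lik_blue_h1) ** (sample_size - k)
            )
        return _clip(expit(lo - prior_lo))
    return _clip(expit(lo))


def _weighted_prob_matrix(
    lo: np.ndarray, gamma: np.ndarray, p0: np.ndarray
) -> np.ndarray:
    """Response-probability matrix, shape ``(len(gamma), len(lo))``.

    Row i holds logistic(gamma_i * Lo_k + (1 - gamma_i) * Lo(p0_i)) over the
    blue counts k.
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    offset = (1.0 - gamma) * log_odds(p0)
    return _clip(expit(gamma[:, None] * lo[None, :] + offset[:, None]))


def response_probability(
    model: ModelSpec | str,
    cond: Condition,
    ev: EvidenceSummary,
    params: WeightingParams | None = None,
) -> float:
    """Probability that the response is 1 (rare urn) for a single trial."""
    model = get_model(model) if isinstance(model, str) else model
    if model.parameter_free:
        return float(_base_probability(model, cond, ev.sample_size)[ev.n_blue])
    if params is None:
        raise ValueError(f"model {model.name!r} requires weighting parameters")
    lo = _posterior_lo_vector(cond, ev.sample_size)
    return float(_weighted_prob_matrix(lo, params.gamma, params.p0)[0, ev.n_blue])


# ---------------------------------------------------------------------------
# prior densities
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * float(np.log(2.0 * np.pi))


def _log_truncnorm(g, mu, sigma):
    """log density of N(mu, sigma) truncated to [0, inf); -inf below 0."""
    g = np.asarray(g, dtype=float)
    z = (g - mu) / sigma
    out = -0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma) - log_ndtr(mu / sigma)
    return np.where(g >= 0.0, out, -np.inf)


def _log_beta(p, a, b):
    """log beta(a, b) density; -inf outside (0, 1)."""
    p = np.asarray(p, dtype=float)
    inside = (p > 0.0) & (p < 1.0)
    safe = np.where(inside, p, 0.5)
    out = (a - 1.0) * np.log(safe) + (b - 1.0) * np.log1p(-safe) - betaln(a, b)
    return np.where(inside, out, -np.inf)


def log_prior_density(model: ModelSpec | str, params) -> float:
    """Weak-prior log density of one weighting pair.

    gamma ~ N(1, 1) truncated to [0, inf); p0 ~ beta(1, 1).  Returns -inf
    outside the support rather than raising; ``params`` may be a
    :class:`WeightingParams` or a raw ``(gamma, p0)`` pair (which, unlike
    the dataclass, can represent out-of-support values).
    """
    model = get_model(model) if isinstance(model, str) else model
    if model.parameter_free:
        raise ValueError(f"model {model.name!r} has no weighting parameters")
    gamma, p0 = (
        (params.gamma, params.p0)
        if isinstance(params, WeightingParams)
        else params
    )
    lg = _log_truncnorm(gamma, 1.0, 1.0)
    lp = _log_beta(p0, 1.0, 1.0)
    return float(lg + lp)


def log_hyperprior_density(h: HyperParams) -> float:
    """Log density of the hierarchical hyper-priors.

    mu_gamma ~ N(1, 1); sigma_gamma ~ Uniform(0, SIGMA_GAMMA_MAX) (a proper
    stand-in for the flat positive prior); phi ~ beta(1, 1); lam ~
    Pareto(LAM_MIN, shape 1.5), i.e. density proportional to lam^-2.5.
    """
    if not 0.0 < h.sigma_gamma < SIGMA_GAMMA_MAX:
        return -np.inf
    if h.lam < LAM_MIN:
        return -np.inf
    out = float(norm.logpdf(h.mu_gamma, loc=1.0, scale=1.0))
    out += -np.log(SIGMA_GAMMA_MAX)
    out += float(_log_beta(h.phi, 1.0, 1.0))
    out += (
        np.log(PARETO_SHAPE)
        + PARETO_SHAPE * np.log(LAM_MIN)
        - (PARETO_SHAPE + 1.0) * np.log(h.lam)
    )
    return float(out)


# ---------------------------------------------------------------------------
# data layout: sufficient statistics per condition
# ---------------------------------------------------------------------------

@dataclass
class CondData:
    """Sufficient statistics of one condition's trials.

    Trials are exchangeable given (participant, blue count), so the
    likelihood of any model depends on the data only through the response
    count tables ``c1``/``c0`` (participants x blue counts).  The per-trial
    index arrays are kept for pointwise log-likelihoods.
    """

    cond: Condition
    participants: list
    sample_size: int
    c1: np.ndarray  # (I, K+1) count of response==1
    c0: np.ndarray  # (I, K+1) count of response==0
    y: np.ndarray  # (N,) responses in original row order
    p_idx: np.ndarray  # (N,) participant index per trial
    k_idx: np.ndarray  # (N,) blue count per trial
    lo: np.ndarray = field(init=False)  # (K+1,) exact posterior log-odds

    def __post_init__(self) -> None:
        self.lo = _posterior_lo_vector(self.cond, self.sample_size)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_trials(self) -> int:
        return self.y.size

    @classmethod
    def from_frame(
        cls, data: pd.DataFrame, cond: Condition, sample_size: int = 4
    ) -> "CondData":
        """Build from a trial table (one condition's rows)."""
        if "condition" in data.columns:
            sub = data[data["condition"] == cond.label]
            if len(sub) < len(data):
                data = sub
        if data.empty:
            raise ValueError(f"no trials for condition {cond.label!r}")
        participants = sorted(data["participant_id"].unique().tolist())
        pid_map = {p: i for i, p in enumerate(participants)}
        p_idx = data["participant_id"].map(pid_map).to_numpy()
        k_idx = data["n_blue"].to_numpy(dtype=int)
        y = data["response"].to_numpy(dtype=int)
        if k_idx.min() < 0 or k_idx.max() > sample_size:
            raise ValueError("n_blue outside 0..sample_size")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("responses must be 0 or 1")
        nk = sample_size + 1
        c1 = np.zeros((len(participants), nk))
        c0 = np.zeros((len(participants), nk))
        np.add.at(c1, (p_idx, k_idx), y)
        np.add.at(c0, (p_idx, k_idx), 1 - y)
        return cls(cond, participants, sample_size, c1, c0, y, p_idx, k_idx)

    def loglik_from_matrix(self, prob: np.ndarray) -> float:
        """Total Bernoulli log-likelihood given a (I, K+1) probability matrix."""
        return float(
            np.sum(self.c1 * np.log(prob)) + np.sum(self.c0 * np.log1p(-prob))
        )

    def pointwise_from_matrix(self, prob: np.ndarray) -> np.ndarray:
        """Per-trial log-likelihood vector from a (I, K+1) probability matrix."""
        q = prob[self.p_idx, self.k_idx]
        return np.where(self.y == 1, np.log(q), np.log1p(-q))


def _prob_matrix_for(
    model: ModelSpec, cd: CondData, params, broadcast_shared: bool = True
) -> np.ndarray:
    """Response-probability matrix (I, K+1) for any model/parameter pairing."""
    if model.parameter_free:
        base = _base_probability(model, cd.cond, cd.sample_size)
        return np.tile(base, (cd.n_participants, 1))
    if isinstance(params, WeightingParams):
        row = _weighted_prob_matrix(cd.lo, params.gamma, params.p0)
        return np.tile(row, (cd.n_participants, 1)) if broadcast_shared else row
    # per-individual mapping participant -> WeightingParams
    missing = [p for p in cd.participants if p not in params]
    extra = [p for p in params if p not in cd.participants]
    if missing or extra:
        raise ValueError(
            f"participants in data and params differ (missing={missing}, "
            f"extra={extra})"
        )
    gamma = np.array([params[p].gamma for p in cd.participants])
    p0 = np.array([params[p].p0 for p in cd.participants])
    return _weighted_prob_matrix(cd.lo, gamma, p0)


def _individual_arrays(cd: CondData, params) -> tuple[np.ndarray, np.ndarray]:
    gamma = np.array([params[p].gamma for p in cd.participants])
    p0 = np.array([params[p].p0 for p in cd.participants])
    return gamma, p0


def _as_cond_data(data, cond: Condition, sample_size: int = 4) -> CondData:
    if isinstance(data, CondData):
        return data
    if isinstance(data, pd.DataFrame):
        return CondData.from_frame(data, cond, sample_size)
    # list of TrialRecord
    frame = pd.DataFrame(
        {
            "participant_id": [t.participant for t in data],
            "condition": [t.condition for t in data],
            "n_blue": [t.n_blue for t in data],
            "response": [t.response for t in data],
        }
    )
    return CondData.from_frame(frame, cond, sample_size)


# ---------------------------------------------------------------------------
# joint and pointwise log densities
# ---------------------------------------------------------------------------

def log_joint(
    model: ModelSpec | str,
    data,
    cond: Condition,
    params=None,
    hyper: HyperParams | None = None,
    sample_size: int = 4,
) -> float:
    """Unnormalized log posterior: Bernoulli log-likelihood + log priors.

    ``data`` may be a trial DataFrame, a list of :class:`TrialRecord`, a
    prepared :class:`CondData`, or ``None``/empty for the prior alone.
    Parameter structure must match the model: a shared
    :class:`WeightingParams` for ``weighted_pooled``, a participant ->
    :class:`WeightingParams` mapping for the individual-difference models,
    plus :class:`HyperParams` for the hierarchical model.
    """
    model = get_model(model) if isinstance(model, str) else model
    empty = data is None or (hasattr(data, "__len__") and len(data) == 0)
    cd = None if empty else _as_cond_data(data, cond, sample_size)

    ll = 0.0
    if cd is not None:
        prob = _prob_matrix_for(model, cd, params)
        ll = cd.loglik_from_matrix(prob)

    if model.parameter_free:
        return ll

    if model.name == "weighted_pooled":
        if not isinstance(params, WeightingParams):
            raise ValueError("weighted_pooled expects a single WeightingParams")
        return ll + log_prior_density(model, params)

    if not isinstance(params, dict):
        raise ValueError(f"{model.name} expects a participant -> params mapping")
    if cd is None:
        gamma = np.array([w.gamma for w in params.values()])
        p0 = np.array([w.p0 for w in params.values()])
    else:
        gamma, p0 = _individual_arrays(cd, params)

    if model.hierarchical:
        if hyper is None:
            raise ValueError("weighted_hierarchical requires HyperParams")
        lp = float(np.sum(_log_truncnorm(gamma, hyper.mu_gamma, hyper.sigma_gamma)))
        lp += float(np.sum(_log_beta(p0, hyper.alpha, hyper.beta)))
        lp += log_hyperprior_density(hyper)
    else:
        lp = float(np.sum(_log_truncnorm(gamma, 1.0, 1.0)))
        lp += float(np.sum(_log_beta(p0, 1.0, 1.0)))
    return ll + lp


def pointwise_log_likelihood(
    model: ModelSpec | str,
    data,
    cond: Condition,
    params=None,
    hyper: HyperParams | None = None,
    sample_size: int = 4,
) -> np.ndarray:
    """Per-trial log-likelihood vector ``ln p(y_n | theta)``.

    Sums exactly to the likelihood part of :func:`log_joint`.  ``hyper`` is
    accepted for signature symmetry but does not enter the data likelihood.
    """
    model = get_model(model) if isinstance(model, str) else model
    cd = _as_cond_data(data, cond, sample_size)
    prob = _prob_matrix_for(model, cd, params)
    return cd.pointwise_from_matrix(prob)
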