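"""The urn-ball task and its ideal observer.

Two urn types :math:`H_1` (rare) and :math:`H_2` (common) differ in their
proportion of blue balls.  On each trial one urn is drawn according to the
prior base rates, a sample of ``K`` balls is drawn from it with replacement,
and the observer must infer which urn generated the sample.  Because draws
are i.i.d. Bernoulli given the urn, the number of blue balls is a sufficient
statistic and the posterior log-odds are additive in per-ball log likelihood
ratios:

.. math::

    \\mathrm{Lo}(P(H_1|E)) = \\ln\\frac{P(H_1)}{P(H_2)}
        + \\sum_{k=1}^{K} \\ln\\frac{P(e_k|H_1)}{P(e_k|H_2)}.

This module computes exact posterior probabilities and log-odds (the ideal
observer) for arbitrary conditions, and builds the reference table of all
``(condition, n_blue)`` cells used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "Condition",
    "EvidenceSummary",
    "PosteriorResult",
    "PAPER_CONDITIONS",
    "CLIP",
    "clip_probability",
    "log_odds",
    "logistic",
    "posterior_log_odds",
    "posterior_probability",
    "build_reference_table",
]

#: Probabilities are clipped to [CLIP, 1 - CLIP] before taking log-odds so
#: that downstream log-likelihoods stay finite.  The clip is far below any
#: probability arising in the 4-ball design, so reference values are exact.
CLIP = 1e-12


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design: a prior base rate plus likelihoods.

    Parameters
    ----------
    label
        Short name, e.g. ``"PcLc"`` (certain prior, certain likelihood).
    prior_h1
        Base rate of the rare urn :math:`H_1`; :math:`P(H_2) = 1 - P(H_1)`
        is always derived, never stored.
    lik_blue_h1, lik_blue_h2
        Probability that a single drawn ball is blue under each urn type.
        In the classic design the urns are mirrored
        (``lik_blue_h2 == 1 - lik_blue_h1``) but this is not required.
    """

    label: str
    prior_h1: float
    lik_blue_h1: float
    lik_blue_h2: float

    def __post_init__(self) -> None:
        for name in ("prior_h1", "lik_blue_h1", "lik_blue_h2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")

    @property
    def prior_h2(self) -> float:
        return 1.0 - self.prior_h1


@dataclass(frozen=True)
class EvidenceSummary:
    """A ball sample summarised by its count of blue balls out of ``sample_size``."""

    n_blue: int
    sample_size: int = 4

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if not 0 <= self.n_blue <= self.sample_size:
            raise ValueError(
                f"n_blue must be in 0..{self.sample_size}, got {self.n_blue}"
            )


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior probability of the rare urn and the matching log-odds."""

    p_h1: float
    log_odds_h1: float


#: The study's four conditions: prior P(H1) in {0.1, 0.3} crossed with
#: blue-ball likelihood P(blue|H1) in {0.9, 0.7}, urns mirrored.
PAPER_CONDITIONS: dict[str, Condition] = {
    "PcLc": Condition("PcLc", 0.1, 0.9, 0.1),
    "PuLc": Condition("PuLc", 0.3, 0.9, 0.1),
    "PcLu": Condition("PcLu", 0.1, 0.7, 0.3),
    "PuLu": Condition("PuLu", 0.3, 0.7, 0.3),
}


def clip_probability(p):
    """Clip ``p`` into ``[CLIP, 1 - CLIP]`` (array-aware)."""
    return np.clip(p, CLIP, 1.0 - CLIP)


def log_odds(p):
    """Natural-log odds ``ln(p / (1 - p))``, the inverse of :func:`logistic`.

    ``p`` is clipped to ``[CLIP, 1 - CLIP]`` first; values that are exactly
    0 or 1 *after* clipping (i.e. non-probabilities) raise ``ValueError``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)) or np.any(~np.isfinite(p)):
        raise ValueError("log_odds requires probabilities in [0, 1]")
    p = clip_probability(p)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def logistic(x):
    """Logistic function ``1 / (1 + exp(-x))``; saturates gracefully."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def posterior_log_odds(cond: Condition, ev: EvidenceSummary) -> float:
    """Exact posterior log-odds of :math:`H_1` given a ball sample.

    Adds the prior log-odds to one log likelihood ratio per ball; the order
    of the draws is irrelevant, so only the blue count enters.
    """
    if not (0.0 < cond.lik_blue_h1 < 1.0 and 0.0 < cond.lik_blue_h2 < 1.0):
        raise ValueError("degenerate likelihoods (0 or 1) are not supported")
    lr_blue = np.log(cond.lik_blue_h1) - np.log(cond.lik_blue_h2)
    lr_red = np.log1p(-cond.lik_blue_h1) - np.log1p(-cond.lik_blue_h2)
    prior_lo = np.log(cond.prior_h1) - np.log(cond.prior_h2)
    n_red = ev.sample_size - ev.n_blue
    return float(prior_lo + ev.n_blue * lr_blue + n_red * lr_red)


def posterior_probability(cond: Condition, ev: EvidenceSummary) -> PosteriorResult:
    """Posterior probability of the rare urn, via the log-odds form."""
    lo = posterior_log_odds(cond, ev)
    return PosteriorResult(p_h1=logistic(lo), log_odds_h1=lo)


def build_reference_table(
    conditions=None, sample_size: int = 4
) -> pd.DataFrame:
    """All ``(condition, n_blue)`` posterior cells as a tidy DataFrame.

    Columns: ``condition, n_blue, p_h1, log_odds_h1`` with one row per
    blue-ball count (0..K) per condition.  With the four study conditions
    and K=4 this is the 20-entry ideal-observer reference table.
    """
    if conditions is None:
        conditions = list(PAPER_CONDITIONS.values())
    if not conditions:
        raise ValueError("need at least one condition")
    rows = []
    for cond in conditions:
        for k in range(sample_size + 1):
            res = posterior_probability(cond, EvidenceSummary(k, sample_size))
            rows.append(
                {
                    "condition": cond.label,
                    "n_blue": k,
                    "p_h1": res.p_h1,
                    "log_odds_h1": res.log_odds_h1,
                }
            )
    return pd.DataFrame(rows)
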