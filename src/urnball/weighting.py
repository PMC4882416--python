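"""Linear-in-log-odds probability weighting.

A subjective probability :math:`\\pi` is a distorted version of an objective
probability :math:`p`, linear in log-odds space:

.. math::

    \\pi = \\mathrm{logistic}\\bigl(\\gamma\\,\\mathrm{Lo}(p)
          + (1-\\gamma)\\,\\mathrm{Lo}(p_0)\\bigr)

with slope :math:`\\gamma \\ge 0` and crossover point :math:`p_0 \\in (0,1)`
where :math:`\\pi(p_0)=p_0`.  :math:`\\gamma=1` leaves probabilities
untransformed; :math:`\\gamma<1` yields the inverse-S shape familiar from
prospect theory (small probabilities inflated, large ones deflated),
:math:`\\gamma>1` the opposite S shape.

Because the distortion is linear in log-odds, weighting a Bayesian posterior
is the same as weighting the prior log-odds and each log likelihood ratio by
:math:`\\gamma` and adding the :math:`(1-\\gamma)\\,\\mathrm{Lo}(p_0)` offset
once — subjective belief updating stays additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import Condition, EvidenceSummary, log_odds, logistic, posterior_log_odds

__all__ = [
    "WeightingParams",
    "weight_probability",
    "weight_log_odds",
    "weighted_posterior_log_odds",
    "weighting_curve",
]


@dataclass(frozen=True)
class WeightingParams:
    """Slope ``gamma`` (>= 0) and crossover point ``p0`` in the open (0, 1)."""

    gamma: float
    p0: float

    def __post_init__(self) -> None:
        if not self.gamma >= 0.0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        # boundary p0 would make Lo(p0) infinite
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie strictly in (0, 1), got {self.p0}")


def weight_log_odds(lo, w: WeightingParams):
    """Apply the weighting directly in log-odds space (array-aware)."""
    return w.gamma * np.asarray(lo, dtype=float) + (1.0 - w.gamma) * log_odds(w.p0)


def weight_probability(p, w: WeightingParams):
    """Subjective probability ``pi`` for objective probability ``p``."""
    return logistic(weight_log_odds(log_odds(p), w))


def weighted_posterior_log_odds(
    cond: Condition, ev: EvidenceSummary, w: WeightingParams
) -> float:
    """Subjective posterior log-odds of the rare urn under weighting.

    Algebraically identical to ``log_odds(weight_probability(P(H1|E), w))``:
    the slope multiplies the prior log-odds and the summed per-ball log
    likelihood ratios, and the crossover offset is added once.
    """
    return float(weight_log_odds(posterior_log_odds(cond, ev), w))


def weighting_curve(
    w: WeightingParams, n_points: int = 99
) -> pd.DataFrame:
    """Sample the weighting function on an interior grid of ``p``.

    Returns a DataFrame with columns ``p`` and ``pi``, convenient for
    plotting or CSV export of the distortion curve.
    """
    p = np.linspace(0.0, 1.0, n_points + 2)[1:-1]
    return pd.DataFrame({"p": p, "pi": weight_probability(p, w)})
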