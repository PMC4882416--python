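"""Linear-in-log-odds probability weighting curves.

Evaluates the subjective-probability distortion pi(p) for an S-shaped
(slope 1.8) and an inverse-S (slope 0.4) parameterization, showing the
fixed point at the crossover p0 and the over/under-weighting pattern.
"""

import numpy as np

from urnball import WeightingParams, weight_probability

for gamma, p0 in [(1.8, 0.67), (0.4, 0.31)]:
    w = WeightingParams(gamma, p0)
    shape = "S-shaped (extremes exaggerated)" if gamma > 1 else \
        "inverse-S (extremes moderated)"
    print(f"\ngamma={gamma}, p0={p0}: {shape}")
    for p in np.round(np.arange(0.1, 1.0, 0.2), 2):
        print(f"  p={p:.2f} -> pi={weight_probability(float(p), w):.5f}")
    print(f"  fixed point: pi({p0}) = {weight_probability(p0, w):.5f}")

print(
    "\npi > p below the crossover and pi < p above it when the slope is "
    "below 1, and the reverse above 1; slope 1 leaves probabilities "
    "untransformed."
)
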