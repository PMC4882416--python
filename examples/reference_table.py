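"""The exact Bayesian observer for the urn-ball task.

Builds the 20-cell reference table of posterior probabilities and log-odds
of the rare urn H1 for every (condition, blue-count) combination of the
2x2 factorial design with 4-ball samples.
"""

from urnball import build_reference_table

table = build_reference_table()
print(table.round(5).to_string(index=False))

print(
    "\nEach row is the ideal observer's belief after one sample: p_h1 is the "
    "posterior probability of the rare urn H1, log_odds_h1 the same belief "
    "in natural-log odds.  In PuLu with 2 of 4 blue balls the likelihood "
    "ratio cancels and the posterior equals the prior, 0.3."
)
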