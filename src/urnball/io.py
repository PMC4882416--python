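"""Trial-table CSV schema and validated reading/writing.

The on-disk format is one RFC-4180 CSV row per trial with header
``participant_id, condition, trial_index, n_blue, response``.  Reading is
strict: missing columns, out-of-range counts or responses, and unknown
condition labels are reported with the offending CSV line numbers rather
than silently coerced.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .task import PAPER_CONDITIONS

__all__ = ["TRIAL_COLUMNS", "TrialTableError", "read_trials", "write_trials"]

TRIAL_COLUMNS = ["participant_id", "condition", "trial_index", "n_blue", "response"]


class TrialTableError(ValueError):
    """A trial CSV violated the schema; the message lists the bad rows."""


def _lines(mask, data) -> str:
    # +2: one for the header line, one for 0-based indexing
    nums = (data.index[mask] + 2).tolist()
    shown = ", ".join(str(n) for n in nums[:10])
    more = f" (+{len(nums) - 10} more)" if len(nums) > 10 else ""
    return shown + more


def read_trials(
    path, sample_size: int = 4, extra_conditions=()
) -> pd.DataFrame:
    """Read and validate a trial table.

    ``extra_conditions`` registers custom condition labels beyond the four
    study cells.  An empty file with a valid header yields an empty table.
    """
    path = Path(path)
    data = pd.read_csv(path, dtype={"participant_id": str, "condition": str})
    missing = [c for c in TRIAL_COLUMNS if c not in data.columns]
    if missing:
        raise TrialTableError(f"{path}: missing required columns {missing}")
    data = data[TRIAL_COLUMNS]
    if data.empty:
        return data
    data = data.reset_index(drop=True)

    for col in ("trial_index", "n_blue", "response"):
        if not pd.api.types.is_integer_dtype(data[col]):
            coerced = pd.to_numeric(data[col], errors="coerce")
            bad = coerced.isna() | (coerced != coerced.round())
            if bad.any():
                raise TrialTableError(
                    f"{path}: non-integer {col} at line(s) {_lines(bad, data)}"
                )
            data[col] = coerced.astype(int)

    bad = ~data["response"].isin((0, 1))
    if bad.any():
        raise TrialTableError(
            f"{path}: response must be 0 or 1 at line(s) {_lines(bad, data)}"
        )
    bad = (data["n_blue"] < 0) | (data["n_blue"] > sample_size)
    if bad.any():
        raise TrialTableError(
            f"{path}: n_blue outside 0..{sample_size} at line(s) "
            f"{_lines(bad, data)}"
        )
    known = set(PAPER_CONDITIONS) | set(extra_conditions)
    bad = ~data["condition"].isin(known)
    if bad.any():
        labels = sorted(data.loc[bad, "condition"].unique())
        raise TrialTableError(
            f"{path}: unknown condition label(s) {labels} at line(s) "
            f"{_lines(bad, data)}"
        )
    return data


def write_trials(data: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical column order (lossless round trip)."""
    missing = [c for c in TRIAL_COLUMNS if c not in data.columns]
    if missing:
        raise TrialTableError(f"cannot write trial table: missing {missing}")
    data[TRIAL_COLUMNS].to_csv(path, index=False)
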