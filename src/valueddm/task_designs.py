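"""Trial grids for the temporal-discounting (TD) and risky-choice (PD) tasks.

TD trials pit a $10 smaller-sooner (SS) reward against larger-later (LL)
rewards built from the full factorial of amounts x delays, presented twice:
once with the SS reward available immediately (*now*, condition_I = 0) and
once with 30 days added to both options (*not now*, condition_I = 1).  PD
trials pit a certain $10 reward against the full factorial of risky amounts
x win probabilities.  Money is in decimal dollars, time in days.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

#: reward amounts of the larger-later option (dollars)
TD_AMOUNTS = (10.1, 10.2, 10.5, 11, 12, 15, 18, 20, 30, 40, 70, 100, 130, 150)
#: delays of the larger-later option in the *now* condition (days)
TD_DELAYS = (1, 3, 5, 8, 14, 30, 60)
#: extra delay added to both options in the *not now* condition (days)
TD_SHIFT_DAYS = 30
#: amount of the smaller-sooner / safe reference option (dollars)
SS_AMOUNT = 10.0

#: reward amounts of the risky option (dollars)
PD_AMOUNTS = (10.1, 10.2, 10.5, 11, 12, 15, 18, 20, 25, 30, 40, 50, 70, 100, 130, 150)
#: win probabilities of the risky option
PD_PROBABILITIES = (0.10, 0.17, 0.28, 0.54, 0.84, 0.96, 0.99)

TD_COLUMNS = [
    "task",
    "trial_index",
    "amount_ss",
    "amount_ll",
    "delay_ss",
    "delay_ll",
    "condition_I",
    "iri",
]
PD_COLUMNS = ["task", "trial_index", "amount_safe", "amount_risky", "probability"]


def generate_td_design(
    amounts: Sequence[float] = TD_AMOUNTS,
    delays: Sequence[float] = TD_DELAYS,
    shift_days: float = TD_SHIFT_DAYS,
    repeat_to: int | None = None,
) -> pd.DataFrame:
    """Full factorial TD trial table: amounts x delays x {now, not now}.

    ``repeat_to`` optionally cycles the grid deterministically to a larger
    stated trial total.  Deterministic row order (condition-major, then
    amount-major, then delay).
    """
    amounts = np.asarray(amounts, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if amounts.size == 0 or delays.size == 0:
        raise ValueError("amounts and delays must be non-empty")
    if np.any(amounts <= 0) or np.any(delays <= 0):
        raise ValueError("amounts and delays must be strictly positive")
    if shift_days < 0:
        raise ValueError("shift_days must be non-negative")

    rows = []
    for cond in (0, 1):
        base = cond * shift_days
        for a in amounts:
            for d in delays:
                rows.append((a, base, base + d, cond, d))
    if repeat_to is not None:
        if repeat_to < len(rows):
            raise ValueError("repeat_to smaller than the factorial grid")
        rows = [rows[i % len(rows)] for i in range(repeat_to)]
    df = pd.DataFrame(rows, columns=["amount_ll", "delay_ss", "delay_ll", "condition_I", "iri"])
    df.insert(0, "task", "TD")
    df.insert(1, "trial_index", np.arange(len(df)))
    df.insert(2, "amount_ss", SS_AMOUNT)
    return df[TD_COLUMNS]


def generate_pd_design(
    amounts: Sequence[float] = PD_AMOUNTS,
    probabilities: Sequence[float] = PD_PROBABILITIES,
) -> pd.DataFrame:
    """Full factorial PD trial table; the safe option is $10 at p = 1."""
    amounts = np.asarray(amounts, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    if amounts.size == 0 or probabilities.size == 0:
        raise ValueError("amounts and probabilities must be non-empty")
    if np.any(amounts <= 0):
        raise ValueError("amounts must be strictly positive")
    if np.any((probabilities <= 0) | (probabilities > 1)):
        raise ValueError("probabilities must lie in (0, 1]")

    rows = [(a, p) for a in amounts for p in probabilities]
    df = pd.DataFrame(rows, columns=["amount_risky", "probability"])
    df.insert(0, "task", "PD")
    df.insert(1, "trial_index", np.arange(len(df)))
    df.insert(2, "amount_safe", SS_AMOUNT)
    return df[PD_COLUMNS]


def randomize_order(trials: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Seeded permutation of the trial rows (trial_index is rewritten)."""
    rng = np.random.default_rng(seed)
    out = trials.iloc[rng.permutation(len(trials))].reset_index(drop=True)
    out["trial_index"] = np.arange(len(out))
    return out


def save_design(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def load_design(path) -> pd.DataFrame:
    return pd.read_csv(path)
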