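"""Subjective-value models for temporal and probability discounting.

Temporal discounting is hyperbolic relative to the soonest available reward:

    SV(LL) = A / (1 + exp(k - I*s) * IRI)

with the discount rate ``k`` carried in log space, an indicator ``I`` for the
*not now* condition, a subject-specific shift ``s`` that reduces log(k) when
both rewards are delayed, and the inter-reward interval ``IRI`` in days.  The
smaller-sooner option sits at the start of the interval (its own IRI is 0) so
its subjective value is its face amount.

Probability discounting is hyperbolic over the odds against winning:

    SV(risky) = A / (1 + exp(h) * theta),   theta = (1 - p) / p

with the probability discount rate ``h`` in log space.  Both functions are
vectorized over trial tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def sv_temporal(trials: pd.DataFrame, log_k_now: float, shift_logk: float) -> np.ndarray:
    """Subjective value of the larger-later option for each TD trial."""
    iri = np.asarray(trials["iri"], dtype=float)
    if np.any(iri < 0):
        raise ValueError("inter-reward interval must be non-negative")
    amount = np.asarray(trials["amount_ll"], dtype=float)
    cond = np.asarray(trials["condition_I"], dtype=float)
    return amount / (1.0 + np.exp(log_k_now - cond * shift_logk) * iri)


def odds_against(p) -> np.ndarray | float:
    """Odds against winning, theta = (1 - p) / p, for p in (0, 1]."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr > 1)):
        raise ValueError("probabilities must lie in (0, 1]")
    theta = (1.0 - p_arr) / p_arr
    return float(theta) if np.isscalar(p) else theta


def sv_risky(trials: pd.DataFrame, log_h: float) -> np.ndarray:
    """Subjective value of the risky option for each PD trial."""
    theta = odds_against(np.asarray(trials["probability"], dtype=float))
    amount = np.asarray(trials["amount_risky"], dtype=float)
    return amount / (1.0 + np.exp(log_h) * theta)


def sv_reference(trials: pd.DataFrame) -> np.ndarray:
    """Subjective value of the smaller-sooner / safe option (its face amount)."""
    col = "amount_ss" if "amount_ss" in trials.columns else "amount_safe"
    return np.asarray(trials[col], dtype=float)


def sv_difference(trials: pd.DataFrame, log_k_now: float = 0.0,
                  shift_logk: float = 0.0, log_h: float = 0.0) -> np.ndarray:
    """SV(LL or risky) - SV(SS or safe) for a single-task trial table."""
    task = trials["task"].iloc[0]
    if task == "TD":
        sv = sv_temporal(trials, log_k_now, shift_logk)
    elif task == "PD":
        sv = sv_risky(trials, log_h)
    else:
        raise ValueError(f"unknown task {task!r}")
    return sv - sv_reference(trials)
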