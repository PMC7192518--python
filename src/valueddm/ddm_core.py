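"""Choice rules: softmax, drift-rate mappings, the Wiener first-passage-time
likelihood, absorption probabilities, trial simulation and RT trimming.

Boundary convention (stimulus coding): the upper boundary is a choice of the
larger-later / risky option, the lower boundary the smaller-sooner / safe
option.  Response times are in seconds; signed RTs are negative for
lower-boundary choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _wfpt

#: sampling bounds of the DDM parameters (group-mean prior supports)
PARAM_BOUNDS = {
    "alpha": (0.01, 5.0),
    "tau": (0.1, 6.0),
    "z": (0.1, 0.9),
    "v_coeff": (-100.0, 100.0),
    "v_max": (0.0, 100.0),
}

CHOICE_COLUMNS = ["subject_id", "trial_index", "boundary", "rt", "signed_rt"]


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters of one subject.

    alpha: boundary separation (evidence units); tau: non-decision time (s);
    z: relative start point in (0, 1); v_max: drift asymptote (evidence/s);
    v_coeff: value-difference scaling (evidence/s per dollar).
    """

    alpha: float
    tau: float
    z: float
    v_coeff: float = 0.0
    v_max: float = 1.0

    def validate(self) -> "DDMParams":
        if not self.alpha > 0:
            raise ValueError("boundary separation must be positive")
        if not self.tau > 0:
            raise ValueError("non-decision time must be positive")
        if not 0 < self.z < 1:
            raise ValueError("relative start point must lie in (0, 1)")
        if not self.v_max > 0:
            raise ValueError("drift asymptote must be positive")
        if not np.isfinite(self.v_coeff):
            raise ValueError("drift scaling must be finite")
        return self


def softmax_p_choice(sv_a, sv_b, beta: float):
    """Probability of choosing option a under softmax action selection.

    Numerically stable for large |beta * SV|; beta = 0 gives chance level.
    """
    x = beta * (np.asarray(sv_a, dtype=float) - np.asarray(sv_b, dtype=float))
    # stable logistic
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, None, 700))),
                   np.exp(np.clip(x, -700, None)) / (1.0 + np.exp(np.clip(x, -700, None))))
    return float(out) if out.ndim == 0 else out


def drift_linear(sv_diff, v_coeff: float):
    """Linear drift map: v = v_coeff * (SV_upper - SV_lower)."""
    return v_coeff * np.asarray(sv_diff, dtype=float)


def drift_sigmoid(sv_diff, v_coeff: float, v_max: float):
    """Sigmoidal drift map, odd in sv_diff with asymptotes at +/- v_max.

    v = S(v_coeff * sv_diff),  S(m) = 2 v_max / (1 + e^{-m}) - v_max.
    """
    if not v_max > 0:
        raise ValueError("drift asymptote must be positive")
    m = np.asarray(v_coeff * np.asarray(sv_diff, dtype=float))
    return 2.0 * v_max / (1.0 + np.exp(-np.clip(m, -700, 700))) - v_max


def wfpt_logdensity(signed_rt, params: DDMParams, drift):
    """Log joint density of (boundary, rt) under the Wiener likelihood.

    ``signed_rt``: scalar or array of signed RTs; ``drift``: matching drift
    rate(s).  RTs with magnitude at or below tau get log-density -inf.
    """
    params.validate()
    srt = np.atleast_1d(np.asarray(signed_rt, dtype=float))
    v = np.broadcast_to(np.asarray(drift, dtype=float), srt.shape).astype(float)
    out = _wfpt.wfpt_logpdf_vec(
        np.ascontiguousarray(srt), np.ascontiguousarray(v),
        params.alpha, params.tau, params.z,
    )
    return float(out[0]) if np.isscalar(signed_rt) else out


def p_upper(params: DDMParams, drift: float) -> float:
    """Closed-form probability of absorption at the upper boundary."""
    params.validate()
    return _wfpt.prob_upper(float(drift), params.alpha, params.z)


def simulate_trials(
    params: DDMParams,
    drift,
    seed: int,
    dt: float = 0.001,
    max_time: float = 30.0,
) -> pd.DataFrame:
    """Euler–Maruyama simulation, one trial per drift entry.

    Walks that fail to absorb within ``max_time`` are flagged ``censored``
    and should be excluded downstream.  Same seed, same output.
    """
    params.validate()
    v = np.ascontiguousarray(np.atleast_1d(np.asarray(drift, dtype=float)))
    boundary, rt = _wfpt.simulate_fpt_batch(
        v, params.alpha, params.tau, params.z, dt, max_time, int(seed) % (2**31)
    )
    df = pd.DataFrame(
        {
            "trial_index": np.arange(v.size),
            "boundary": np.where(boundary == 1, "upper", "lower"),
            "rt": rt,
            "censored": boundary < 0,
        }
    )
    df["signed_rt"] = np.where(boundary == 1, rt, -rt)
    return df


def simulate_trial(params: DDMParams, drift: float, seed: int, **kw) -> tuple[str, float]:
    """Single-trial convenience wrapper; returns (boundary, rt)."""
    row = simulate_trials(params, [drift], seed, **kw).iloc[0]
    return str(row["boundary"]), float(row["rt"])


def trim_rts(data: pd.DataFrame, fraction: float = 0.025) -> pd.DataFrame:
    """Drop, per subject, trials with |rt| strictly outside the central
    [fraction, 1 - fraction] quantile band (linear-interpolation quantiles).

    This is the trimming applied before likelihood evaluation; the default
    removes the fastest and slowest 2.5% of each subject's trials.
    """
    if len(data) == 0:
        raise ValueError("cannot trim an empty table")
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must lie in [0, 0.5)")
    if fraction == 0:
        return data.copy()

    def _trim(group: pd.DataFrame) -> pd.DataFrame:
        rt = group["rt"].abs()
        lo, hi = rt.quantile([fraction, 1 - fraction])
        return group[(rt >= lo) & (rt <= hi)]

    if "subject_id" in data.columns:
        out = data.groupby("subject_id", group_keys=False)[data.columns].apply(_trim)
    else:
        out = _trim(data)
    return out.reset_index(drop=True)


def absolute_rt_filter(data: pd.DataFrame, lo: float = 0.4, hi: float = 10.0) -> pd.DataFrame:
    """Alternative absolute RT cut-off (lo < rt < hi); not the default rule."""
    rt = data["rt"].abs()
    return data[(rt > lo) & (rt < hi)].reset_index(drop=True)
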