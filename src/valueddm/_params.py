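"""Shared parameter table: names, domains and group-mean priors.

Group-level means get uniform priors over numerically plausible ranges
(the shift in log(k) gets a Gaussian(0, 2) prior); group-level precisions
get gamma(.001, .001) priors; subject-level parameters are truncated
normals around the group mean, truncated at the domain bounds.
"""

from __future__ import annotations

import numpy as np

# name -> (lower, upper, prior_kind); prior_kind: "uniform" over the bounds
# or "normal" (mean 0, sd 2) for the log(k) shift.  The shift is unbounded in
# principle; +/-40 is an effectively non-binding truncation.
PARAM_TABLE: dict[str, tuple[float, float, str]] = {
    "alpha": (0.01, 5.0, "uniform"),
    "tau": (0.1, 6.0, "uniform"),
    "z": (0.1, 0.9, "uniform"),
    "v_coeff": (-100.0, 100.0, "uniform"),
    "v_max": (0.0, 100.0, "uniform"),
    "v": (-100.0, 100.0, "uniform"),          # constant drift of the null DDM
    "log_k_now": (-20.0, 3.0, "uniform"),
    "shift_logk": (-40.0, 40.0, "normal"),
    "log_h": (-10.0, 10.0, "uniform"),
    "lambda_z": (-7.0, 7.0, "uniform"),       # mixture coordinate in z-space
    "beta": (0.0, 10.0, "uniform"),           # softmax inverse temperature
    # null-DDM component of the mixture model
    "alpha_0": (0.01, 5.0, "uniform"),
    "tau_0": (0.1, 6.0, "uniform"),
    "z_0": (0.1, 0.9, "uniform"),
    "v_0": (-100.0, 100.0, "uniform"),
}

SHIFT_PRIOR_SD = 2.0
PRECISION_PRIOR_SHAPE = 0.001
PRECISION_PRIOR_RATE = 0.001

VARIANTS = ("softmax", "ddm0", "ddmlin", "ddms", "mixture")
TASKS = ("TD", "PD")


def param_names(task: str, variant: str) -> list[str]:
    """Subject-level parameter names of a model variant, in sampler order."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    value = ["log_k_now", "shift_logk"] if task == "TD" else ["log_h"]
    if variant == "softmax":
        return ["beta"] + value
    if variant == "ddm0":
        return ["alpha", "tau", "z", "v"]
    if variant == "ddmlin":
        return ["alpha", "tau", "z", "v_coeff"] + value
    if variant == "ddms":
        return ["alpha", "tau", "z", "v_coeff", "v_max"] + value
    if variant == "mixture":
        return (["alpha", "tau", "z", "v_coeff", "v_max"] + value
                + ["alpha_0", "tau_0", "z_0", "v_0", "lambda_z"])
    raise ValueError(f"unknown variant {variant!r}")


def bounds_arrays(names: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lower, upper, prior_is_normal) arrays for a parameter list."""
    lo = np.array([PARAM_TABLE[n][0] for n in names])
    hi = np.array([PARAM_TABLE[n][1] for n in names])
    normal = np.array([PARAM_TABLE[n][2] == "normal" for n in names])
    return lo, hi, normal
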