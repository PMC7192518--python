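"""Low-level Wiener first-passage-time numerics (numba kernels).

The diffusion convention throughout: within-trial diffusion coefficient fixed
at 1, boundary separation ``a`` (evidence units), relative start point
``z`` in (0, 1) (absolute start ``z * a``), drift ``v`` (evidence/s) and
additive non-decision time ``tau`` (s).  Positive drift pushes toward the
upper boundary.  Signed response times are positive for upper-boundary hits
and negative for lower-boundary hits.

The joint density over (boundary, rt) is evaluated with the classical
small-time / large-time series representations of the zero-drift density on
the unit interval, with the term count chosen adaptively so the truncation
error of the series factor is below ``_SERIES_EPS`` per evaluation; the
drift enters through the usual exponential tilting factor.  The
lower-boundary density at drift v and start z equals the upper-boundary
density at drift -v and start 1 - z (reflection), which is how the upper
branch is evaluated.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SERIES_EPS = 1e-12  # absolute truncation error of the series factor


@njit(cache=True)
def _fw_density(tt: float, w: float, eps: float) -> float:
    """Density of first passage to 0 for zero-drift unit diffusion on [0, 1].

    ``tt`` is time normalized by the squared boundary separation, ``w`` the
    relative start point.  Chooses between the small-time and large-time
    series by the number of terms each needs for absolute error ``eps``.
    """
    if tt <= 0.0:
        return 0.0
    # number of terms required by the small-time representation
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    # number of terms required by the large-time representation
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    p = 0.0
    if ks < kl:  # small-time series
        K = int(math.ceil(ks))
        lower = -((K - 1) // 2)
        upper = (K - 1) // 2 + (K - 1) % 2
        for k in range(lower, upper + 1):
            x = w + 2.0 * k
            p += x * math.exp(-x * x / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time series
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    return p


@njit(cache=True)
def wfpt_logpdf(signed_rt: float, v: float, a: float, tau: float, z: float) -> float:
    """Log joint density of (boundary, rt) for one signed response time.

    ``signed_rt > 0`` means the upper boundary was hit at ``rt = signed_rt``;
    ``signed_rt < 0`` the lower boundary at ``rt = -signed_rt``.  Response
    times at or below the non-decision time have density zero (-inf), not an
    error.
    """
    rt = abs(signed_rt)
    t = rt - tau
    if t <= 0.0:
        return -np.inf
    if signed_rt > 0.0:  # upper boundary via reflection
        vv = -v
        w = 1.0 - z
    else:
        vv = v
        w = z
    tt = t / (a * a)
    p = _fw_density(tt, w, _SERIES_EPS)
    if p <= 0.0:
        return -np.inf
    return math.log(p) - 2.0 * math.log(a) - vv * a * w - vv * vv * t / 2.0


@njit(cache=True)
def prob_upper(v: float, a: float, z: float) -> float:
    """Probability of absorption at the upper boundary (closed form).

    Continuous at v = 0 where the limit is z.
    """
    if v < 0.0:
        return 1.0 - prob_upper(-v, a, 1.0 - z)
    x = 2.0 * v * a
    if x < 1e-8:
        # series expansion around v = 0 to avoid 0/0
        return z + v * a * z * (1.0 - z)
    num = -math.expm1(-x * z)
    den = -math.expm1(-x)
    return num / den


@njit(cache=True)
def simulate_fpt_batch(
    v: np.ndarray,
    a: float,
    tau: float,
    z: float,
    dt: float,
    max_time: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Maruyama first-passage simulation, one walk per drift entry.

    Returns (boundary, rt): boundary 1 for upper, 0 for lower, -1 for walks
    censored at ``max_time`` (rt is then max_time + tau).
    """
    np.random.seed(seed)
    n = v.shape[0]
    boundary = np.empty(n, dtype=np.int64)
    rt = np.empty(n, dtype=np.float64)
    sq = math.sqrt(dt)
    max_steps = int(max_time / dt)
    chunk = 256
    for i in range(n):
        x = z * a
        vi = v[i]
        b = -1
        t = max_time
        step = 0
        done = False
        while step < max_steps and not done:
            m = min(chunk, max_steps - step)
            e = np.random.standard_normal(m)
            for j in range(m):
                x += vi * dt + sq * e[j]
                step += 1
                if x >= a:
                    b = 1
                    t = step * dt
                    done = True
                    break
                if x <= 0.0:
                    b = 0
                    t = step * dt
                    done = True
                    break
        boundary[i] = b
        rt[i] = t + tau
    return boundary, rt


@njit(cache=True)
def wfpt_logpdf_vec(
    signed_rt: np.ndarray, v: np.ndarray, a: float, tau: float, z: float
) -> np.ndarray:
    out = np.empty(signed_rt.shape[0])
    for i in range(signed_rt.shape[0]):
        out[i] = wfpt_logpdf(signed_rt[i], v[i], a, tau, z)
    return out
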