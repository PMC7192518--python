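"""Numba kernels for the hierarchical model: per-trial likelihoods and an
adaptive Metropolis-within-Gibbs chain.

Variant codes: 0 softmax, 1 null DDM, 2 linear-drift DDM, 3 sigmoid-drift
DDM, 4 sigmoid/null mixture.  Task codes: 0 temporal discounting (x1 = IRI,
x2 = not-now indicator), 1 risky choice (x1 = odds against winning).

The chain updates every subject-level parameter, every group mean and every
group log-SD with univariate Gaussian random-walk proposals whose scales are
adapted toward 44% acceptance during warm-up (Robbins–Monro, frozen
afterwards).  Group means carry uniform priors over the domain bounds
(Gaussian(0, 2) for the log(k) shift); precisions carry gamma(.001, .001)
priors; subject parameters are normal around the group mean truncated to the
domain bounds, so the hyper-parameter updates include the truncation
normalizer.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._wfpt import wfpt_logpdf

_SQRT2 = math.sqrt(2.0)
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _phi(x: float) -> float:
    if x > 38.0:
        return 1.0
    if x < -38.0:
        return 0.0
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True)
def _log_sigmoid(x: float) -> float:
    if x >= 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(cache=True)
def _sv_diff(task: int, amount: float, ref: float, x1: float, x2: float,
             logk: float, shift: float, logh: float) -> float:
    if task == 0:
        return amount / (1.0 + math.exp(logk - x2 * shift) * x1) - ref
    return amount / (1.0 + math.exp(logh) * x1) - ref


@njit(cache=True)
def _sigmoid_drift(m: float, vmax: float) -> float:
    if m > 700.0:
        m = 700.0
    elif m < -700.0:
        m = -700.0
    return 2.0 * vmax / (1.0 + math.exp(-m)) - vmax


@njit(cache=True)
def trial_loglik(variant: int, task: int, p: np.ndarray, srt: float,
                 amount: float, ref: float, x1: float, x2: float) -> float:
    if variant == 0:  # softmax over the binary choice
        if task == 0:
            svd = _sv_diff(task, amount, ref, x1, x2, p[1], p[2], 0.0)
        else:
            svd = _sv_diff(task, amount, ref, x1, x2, 0.0, 0.0, p[1])
        x = p[0] * svd
        ls = _log_sigmoid(x)
        return ls if srt > 0.0 else ls - x
    if variant == 1:  # null DDM, constant drift
        return wfpt_logpdf(srt, p[3], p[0], p[1], p[2])
    if variant == 2:  # linear drift
        if task == 0:
            svd = _sv_diff(task, amount, ref, x1, x2, p[4], p[5], 0.0)
        else:
            svd = _sv_diff(task, amount, ref, x1, x2, 0.0, 0.0, p[4])
        return wfpt_logpdf(srt, p[3] * svd, p[0], p[1], p[2])
    if task == 0:
        svd = _sv_diff(task, amount, ref, x1, x2, p[5], p[6], 0.0)
    else:
        svd = _sv_diff(task, amount, ref, x1, x2, 0.0, 0.0, p[5])
    v_s = _sigmoid_drift(p[3] * svd, p[4])
    ll_s = wfpt_logpdf(srt, v_s, p[0], p[1], p[2])
    if variant == 3:  # sigmoid drift
        return ll_s
    # mixture: lambda * f_S + (1 - lambda) * f_0, indicator marginalized out
    off = 7 if task == 0 else 6
    ll_0 = wfpt_logpdf(srt, p[off + 3], p[off], p[off + 1], p[off + 2])
    lam = _phi(p[off + 4])
    if lam <= 0.0:
        return ll_0
    if lam >= 1.0:
        return ll_s
    a = math.log(lam) + ll_s
    b = math.log(1.0 - lam) + ll_0
    m = a if a > b else b
    if m == -np.inf:
        return -np.inf
    return m + math.log(math.exp(a - m) + math.exp(b - m))


@njit(cache=True)
def subject_loglik(variant: int, task: int, p: np.ndarray, srt: np.ndarray,
                   amount: np.ndarray, ref: np.ndarray, x1: np.ndarray,
                   x2: np.ndarray, i0: int, i1: int) -> float:
    total = 0.0
    for i in range(i0, i1):
        total += trial_loglik(variant, task, p, srt[i], amount[i], ref[i], x1[i], x2[i])
        if total == -np.inf:
            return -np.inf
    return total


@njit(cache=True)
def pointwise_loglik(variant: int, task: int, theta: np.ndarray,
                     srt: np.ndarray, amount: np.ndarray, ref: np.ndarray,
                     x1: np.ndarray, x2: np.ndarray,
                     subj_ptr: np.ndarray) -> np.ndarray:
    """(n_draws, n_trials) conditional log-likelihood matrix from
    subject-level draws ``theta`` of shape (n_draws, n_subj, n_p)."""
    n_draws = theta.shape[0]
    n_subj = subj_ptr.shape[0] - 1
    out = np.empty((n_draws, srt.shape[0]))
    for d in range(n_draws):
        for s in range(n_subj):
            for i in range(subj_ptr[s], subj_ptr[s + 1]):
                out[d, i] = trial_loglik(variant, task, theta[d, s], srt[i],
                                         amount[i], ref[i], x1[i], x2[i])
    return out


@njit(cache=True)
def _tnorm_lp(x: float, mu: float, sd: float, lo: float, hi: float) -> float:
    z_hi = _phi((hi - mu) / sd)
    z_lo = _phi((lo - mu) / sd)
    zn = z_hi - z_lo
    if zn < 1e-300:
        return -np.inf
    u = (x - mu) / sd
    return -math.log(sd) - _HALF_LOG_2PI - 0.5 * u * u - math.log(zn)


@njit(cache=True)
def run_chain(
    variant: int,
    task: int,
    srt: np.ndarray,
    amount: np.ndarray,
    ref: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    subj_ptr: np.ndarray,
    group: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    prior_normal: np.ndarray,
    shift_prior_sd: float,
    prec_a: float,
    prec_b: float,
    mu_init: np.ndarray,
    ls_init: np.ndarray,
    theta_init: np.ndarray,
    n_warm: int,
    n_keep: int,
    thin: int,
    seed: int,
):
    """One MCMC chain; returns (mu, log_sd, theta) draw arrays."""
    np.random.seed(seed)
    n_subj = subj_ptr.shape[0] - 1
    n_p = lo.shape[0]

    mu = mu_init.copy()
    ls = ls_init.copy()
    theta = theta_init.copy()

    cll = np.empty(n_subj)
    for s in range(n_subj):
        cll[s] = subject_loglik(variant, task, theta[s], srt, amount, ref, x1,
                                x2, subj_ptr[s], subj_ptr[s + 1])

    sc_t = np.full((n_subj, n_p), 0.1)
    sc_mu = np.full((2, n_p), 0.1)
    sc_ls = np.full((2, n_p), 0.1)

    # per-subject empirical covariance (Welford) driving joint proposals
    # along the posterior's correlation ridges
    w_count = 0
    w_mean = np.zeros((n_subj, n_p))
    w_m2 = np.zeros((n_subj, n_p, n_p))
    chol = np.zeros((n_subj, n_p, n_p))
    have_chol = False
    sc_joint = np.full(n_subj, 2.38 / math.sqrt(n_p))

    # scale group-move ("funnel" move): joint proposal of a group SD with a
    # rescaling of that group's subject deviations around the group mean
    sc_funnel = np.full((2, n_p), 0.3)
    sc_shift = np.full((2, n_p), 0.3)
    tmp_theta = np.empty(n_subj)
    tmp_ll = np.empty(n_subj)

    mu_out = np.empty((n_keep, 2, n_p))
    ls_out = np.empty((n_keep, 2, n_p))
    theta_out = np.empty((n_keep, n_subj, n_p))

    total = n_warm + n_keep * thin
    kept = 0
    for it in range(total):
        warm = it < n_warm
        gam = 1.0 / (1.0 + it) ** 0.6 if warm else 0.0

        for s in range(n_subj):
            g = group[s]
            for j in range(n_p):
                cur = theta[s, j]
                prop = cur + sc_t[s, j] * np.random.standard_normal()
                acc = 0.0
                if lo[j] < prop < hi[j]:
                    theta[s, j] = prop
                    ll_new = subject_loglik(variant, task, theta[s], srt,
                                            amount, ref, x1, x2,
                                            subj_ptr[s], subj_ptr[s + 1])
                    theta[s, j] = cur
                    sd = math.exp(ls[g, j])
                    d = (ll_new - cll[s]
                         - 0.5 * ((prop - mu[g, j]) / sd) ** 2
                         + 0.5 * ((cur - mu[g, j]) / sd) ** 2)
                    if d > 0.0:
                        acc = 1.0
                    elif d > -700.0:
                        acc = math.exp(d)
                    if np.random.random() < acc:
                        theta[s, j] = prop
                        cll[s] = ll_new
                if warm:
                    sc_t[s, j] *= math.exp(gam * (acc - 0.44))

        # warm-up covariance accumulation and joint subject-level proposals
        if warm:
            w_count += 1
            for s in range(n_subj):
                for j in range(n_p):
                    dj = theta[s, j] - w_mean[s, j]
                    w_mean[s, j] += dj / w_count
                    for jj in range(n_p):
                        w_m2[s, j, jj] += dj * (theta[s, jj] - w_mean[s, jj])
            if w_count >= 4 * n_p and w_count % 100 == 0:
                for s in range(n_subj):
                    cov = w_m2[s] / (w_count - 1)
                    for j in range(n_p):
                        cov[j, j] += 1e-8 + 1e-6 * cov[j, j]
                    chol[s] = np.linalg.cholesky(cov)
                have_chol = True
        # independence proposals from the group distribution: for weakly
        # identified subject parameters the likelihood is flat and these
        # mix in one step (hierarchical-prior terms cancel exactly)
        for s in range(n_subj):
            g = group[s]
            j = np.random.randint(n_p)
            sd = math.exp(ls[g, j])
            prop = np.nan
            for _try in range(100):
                cand = mu[g, j] + sd * np.random.standard_normal()
                if lo[j] < cand < hi[j]:
                    prop = cand
                    break
            if not np.isnan(prop):
                cur = theta[s, j]
                theta[s, j] = prop
                ll_new = subject_loglik(variant, task, theta[s], srt, amount,
                                        ref, x1, x2, subj_ptr[s], subj_ptr[s + 1])
                d = ll_new - cll[s]
                if d > 0.0 or (d > -700.0 and np.random.random() < math.exp(d)):
                    cll[s] = ll_new
                else:
                    theta[s, j] = cur

        if have_chol:
          for _rep in range(2):
            for s in range(n_subj):
                g = group[s]
                step = sc_joint[s] * (chol[s] @ np.random.standard_normal(n_p))
                ok = True
                for j in range(n_p):
                    pj = theta[s, j] + step[j]
                    if not (lo[j] < pj < hi[j]):
                        ok = False
                        break
                acc = 0.0
                if ok:
                    cur_vec = theta[s].copy()
                    for j in range(n_p):
                        theta[s, j] = cur_vec[j] + step[j]
                    ll_new = subject_loglik(variant, task, theta[s], srt,
                                            amount, ref, x1, x2,
                                            subj_ptr[s], subj_ptr[s + 1])
                    d = ll_new - cll[s]
                    for j in range(n_p):
                        sd = math.exp(ls[g, j])
                        d += (-0.5 * ((theta[s, j] - mu[g, j]) / sd) ** 2
                              + 0.5 * ((cur_vec[j] - mu[g, j]) / sd) ** 2)
                    if d > 0.0:
                        acc = 1.0
                    elif d > -700.0:
                        acc = math.exp(d)
                    if np.random.random() < acc:
                        cll[s] = ll_new
                    else:
                        for j in range(n_p):
                            theta[s, j] = cur_vec[j]
                if warm:
                    sc_joint[s] *= math.exp(gam * (acc - 0.28))

        for g in range(2):
            for j in range(n_p):
                sd = math.exp(ls[g, j])
                # group mean
                cur = mu[g, j]
                prop = cur + sc_mu[g, j] * np.random.standard_normal()
                acc = 0.0
                ok = True
                d = 0.0
                if prior_normal[j]:
                    d = (-0.5 * (prop / shift_prior_sd) ** 2
                         + 0.5 * (cur / shift_prior_sd) ** 2)
                elif not (lo[j] < prop < hi[j]):
                    ok = False
                if ok:
                    for s in range(n_subj):
                        if group[s] == g:
                            d += (_tnorm_lp(theta[s, j], prop, sd, lo[j], hi[j])
                                  - _tnorm_lp(theta[s, j], cur, sd, lo[j], hi[j]))
                    if d > 0.0:
                        acc = 1.0
                    elif d > -700.0:
                        acc = math.exp(d)
                    if np.random.random() < acc:
                        mu[g, j] = prop
                if warm:
                    sc_mu[g, j] *= math.exp(gam * (acc - 0.44))

                # group log-SD (precision = exp(-2 ls))
                cur = ls[g, j]
                prop = cur + sc_ls[g, j] * np.random.standard_normal()
                acc = 0.0
                if -8.0 < prop < 4.0:
                    p_new = math.exp(-2.0 * prop)
                    p_old = math.exp(-2.0 * cur)
                    d = prec_a * (math.log(p_new) - math.log(p_old)) - prec_b * (p_new - p_old)
                    sd_new = math.exp(prop)
                    sd_old = math.exp(cur)
                    for s in range(n_subj):
                        if group[s] == g:
                            d += (_tnorm_lp(theta[s, j], mu[g, j], sd_new, lo[j], hi[j])
                                  - _tnorm_lp(theta[s, j], mu[g, j], sd_old, lo[j], hi[j]))
                    if d > 0.0:
                        acc = 1.0
                    elif d > -700.0:
                        acc = math.exp(d)
                    if np.random.random() < acc:
                        ls[g, j] = prop
                if warm:
                    sc_ls[g, j] *= math.exp(gam * (acc - 0.44))

        # translation group-move: shift a group mean and its subject values
        # together
        for g in range(2):
          for j in range(n_p):
            delta = sc_shift[g, j] * np.random.standard_normal()
            cur_mu = mu[g, j]
            new_mu = cur_mu + delta
            acc = 0.0
            ok = True
            d = 0.0
            if prior_normal[j]:
                d = (-0.5 * (new_mu / shift_prior_sd) ** 2
                     + 0.5 * (cur_mu / shift_prior_sd) ** 2)
            elif not (lo[j] < new_mu < hi[j]):
                ok = False
            n_g = 0
            if ok:
                for s in range(n_subj):
                    if group[s] == g:
                        t_new = theta[s, j] + delta
                        if not (lo[j] < t_new < hi[j]):
                            ok = False
                            break
                        tmp_theta[s] = t_new
                        n_g += 1
            if ok and n_g > 0:
                sd = math.exp(ls[g, j])
                for s in range(n_subj):
                    if group[s] == g:
                        old_t = theta[s, j]
                        theta[s, j] = tmp_theta[s]
                        tmp_ll[s] = subject_loglik(
                            variant, task, theta[s], srt, amount, ref,
                            x1, x2, subj_ptr[s], subj_ptr[s + 1])
                        theta[s, j] = old_t
                        d += (tmp_ll[s] - cll[s]
                              + _tnorm_lp(tmp_theta[s], new_mu, sd, lo[j], hi[j])
                              - _tnorm_lp(theta[s, j], cur_mu, sd, lo[j], hi[j]))
                if d > 0.0:
                    acc = 1.0
                elif d > -700.0:
                    acc = math.exp(d)
                if np.random.random() < acc:
                    mu[g, j] = new_mu
                    for s in range(n_subj):
                        if group[s] == g:
                            theta[s, j] = tmp_theta[s]
                            cll[s] = tmp_ll[s]
            if warm:
                sc_shift[g, j] *= math.exp(gam * (acc - 0.28))

        # Metropolized Gibbs on the group hypers: propose from the
        # untruncated conjugate conditionals; everything cancels in the
        # acceptance ratio except the truncation normalizers, so acceptance
        # is ~1 whenever the domain bounds are non-binding
        for g in range(2):
            for j in range(n_p):
                n_g = 0
                ssum = 0.0
                for s in range(n_subj):
                    if group[s] == g:
                        n_g += 1
                        ssum += theta[s, j]
                if n_g == 0:
                    continue
                # group mean
                sd = math.exp(ls[g, j])
                if prior_normal[j]:
                    post_prec = n_g / (sd * sd) + 1.0 / (shift_prior_sd * shift_prior_sd)
                    post_mean = (ssum / (sd * sd)) / post_prec
                else:
                    post_prec = n_g / (sd * sd)
                    post_mean = ssum / n_g
                cand = post_mean + np.random.standard_normal() / math.sqrt(post_prec)
                if prior_normal[j] or (lo[j] < cand < hi[j]):
                    z_cur = _phi((hi[j] - mu[g, j]) / sd) - _phi((lo[j] - mu[g, j]) / sd)
                    z_new = _phi((hi[j] - cand) / sd) - _phi((lo[j] - cand) / sd)
                    if z_new > 1e-300:
                        d = n_g * (math.log(z_cur) - math.log(z_new))
                        if d > 0.0 or (d > -700.0 and np.random.random() < math.exp(d)):
                            mu[g, j] = cand
                # group precision
                ssq = 0.0
                for s in range(n_subj):
                    if group[s] == g:
                        dev = theta[s, j] - mu[g, j]
                        ssq += dev * dev
                prec_new = np.random.gamma(prec_a + 0.5 * n_g,
                                           1.0 / (prec_b + 0.5 * ssq))
                if prec_new > 0.0:
                    ls_new = -0.5 * math.log(prec_new)
                    if -8.0 < ls_new < 4.0:
                        sd_cur = math.exp(ls[g, j])
                        sd_new = math.exp(ls_new)
                        z_cur = (_phi((hi[j] - mu[g, j]) / sd_cur)
                                 - _phi((lo[j] - mu[g, j]) / sd_cur))
                        z_new = (_phi((hi[j] - mu[g, j]) / sd_new)
                                 - _phi((lo[j] - mu[g, j]) / sd_new))
                        if z_new > 1e-300:
                            d = n_g * (math.log(z_cur) - math.log(z_new))
                            if d > 0.0 or (d > -700.0 and np.random.random() < math.exp(d)):
                                ls[g, j] = ls_new

        # funnel move: joint group-SD / subject-deviation rescaling
        for g in range(2):
          for j in range(n_p):
            cur_ls = ls[g, j]
            delta = sc_funnel[g, j] * np.random.standard_normal()
            new_ls = cur_ls + delta
            acc = 0.0
            if -8.0 < new_ls < 4.0:
                sd_old = math.exp(cur_ls)
                sd_new = math.exp(new_ls)
                ratio = sd_new / sd_old
                ok = True
                n_g = 0
                for s in range(n_subj):
                    if group[s] == g:
                        t_new = mu[g, j] + ratio * (theta[s, j] - mu[g, j])
                        if not (lo[j] < t_new < hi[j]):
                            ok = False
                            break
                        tmp_theta[s] = t_new
                        n_g += 1
                if ok and n_g > 0:
                    p_new = math.exp(-2.0 * new_ls)
                    p_old = math.exp(-2.0 * cur_ls)
                    d = (prec_a * (math.log(p_new) - math.log(p_old))
                         - prec_b * (p_new - p_old)
                         + n_g * math.log(ratio))  # Jacobian of the rescale
                    for s in range(n_subj):
                        if group[s] == g and d > -np.inf:
                            old_t = theta[s, j]
                            theta[s, j] = tmp_theta[s]
                            tmp_ll[s] = subject_loglik(
                                variant, task, theta[s], srt, amount, ref,
                                x1, x2, subj_ptr[s], subj_ptr[s + 1])
                            theta[s, j] = old_t
                            d += (tmp_ll[s] - cll[s]
                                  + _tnorm_lp(tmp_theta[s], mu[g, j], sd_new, lo[j], hi[j])
                                  - _tnorm_lp(theta[s, j], mu[g, j], sd_old, lo[j], hi[j]))
                    if d > 0.0:
                        acc = 1.0
                    elif d > -700.0:
                        acc = math.exp(d)
                    if np.random.random() < acc:
                        ls[g, j] = new_ls
                        for s in range(n_subj):
                            if group[s] == g:
                                theta[s, j] = tmp_theta[s]
                                cll[s] = tmp_ll[s]
            if warm:
                sc_funnel[g, j] *= math.exp(gam * (acc - 0.28))

        if not warm and (it - n_warm + 1) % thin == 0:
            mu_out[kept] = mu
            ls_out[kept] = ls
            theta_out[kept] = theta
            kept += 1

    return mu_out, ls_out, theta_out
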