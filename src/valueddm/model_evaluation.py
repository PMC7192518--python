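"""Model comparison (WAIC / elpd), binary-choice prediction accuracy and
posterior predictive checks.

elpd sign convention: larger elpd = better predictive fit; comparison tables
also report -elpd so that smaller numbers mean better fit, matching the
usual information-criterion reading (WAIC = -2 * elpd_waic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from arviz import psislw
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .ddm_core import DDMParams, drift_sigmoid, p_upper, simulate_trials
from .inference import PosteriorSamples

PSIS_K_WARN = 0.7


def _check_loglik(ll: np.ndarray) -> np.ndarray:
    ll = np.asarray(ll, float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2, trials) log-likelihood matrix")
    if not np.isfinite(ll).all():
        bad = np.nonzero(~np.isfinite(ll).all(axis=0))[0]
        raise ValueError(f"non-finite log-likelihood at trials {bad.tolist()}")
    return ll


def waic(pointwise_loglik: np.ndarray) -> tuple[float, float]:
    """(WAIC, elpd_waic) from a draws x trials log-likelihood matrix.

    elpd_waic = sum_i [ log mean_d exp(ll_di) - var_d(ll_di) ]; the penalty
    is the per-trial posterior variance of the log-likelihood and vanishes
    when all draws agree.  WAIC = -2 * elpd_waic.
    """
    ll = _check_loglik(pointwise_loglik)
    s = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(s)
    penalty = ll.var(axis=0, ddof=1)
    elpd = float(np.sum(lppd - penalty))
    return -2.0 * elpd, elpd


def elpd_loo(pointwise_loglik: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Leave-one-out elpd by Pareto-smoothed importance sampling.

    Returns (elpd, pointwise elpd vector, Pareto k per trial); trials with
    k > 0.7 have unstable importance weights and are flagged, not fatal.
    """
    ll = _check_loglik(pointwise_loglik)
    lw, k = psislw(-ll.T)  # (trials, draws) in, smoothed normalized log-weights out
    pointwise = logsumexp(lw + ll.T, axis=1)
    return float(pointwise.sum()), pointwise, np.asarray(k, float)


def elpd_diff(pointwise_a: np.ndarray, pointwise_b: np.ndarray,
              z: float = 1.96) -> tuple[float, tuple[float, float]]:
    """elpd(a) - elpd(b) with a normal-approximation 95% CI.

    CI half-width = z * sqrt(n) * SD of the pointwise differences.
    """
    a = np.asarray(pointwise_a, float)
    b = np.asarray(pointwise_b, float)
    if a.shape != b.shape:
        raise ValueError("pointwise vectors differ in length")
    d = a - b
    diff = float(d.sum())
    se = float(np.sqrt(d.size) * d.std(ddof=1)) if d.size > 1 else 0.0
    return diff, (diff - z * se, diff + z * se)


def compare(posteriors: dict[str, PosteriorSamples], reference: str | None = None,
            max_draws: int = 1000) -> pd.DataFrame:
    """Comparison table over fitted models: WAIC, elpd (LOO), -elpd, and the
    elpd difference to the reference model (default: highest-elpd model)."""
    point = {}
    rows = {}
    for name, post in posteriors.items():
        ll = post.pointwise_loglik(max_draws=max_draws)
        w, elpd_w = waic(ll)
        el, pw, k = elpd_loo(ll)
        point[name] = pw
        rows[name] = {"WAIC": w, "elpd_waic": elpd_w, "elpd_loo": el,
                      "neg_elpd_loo": -el, "n_bad_k": int((k > PSIS_K_WARN).sum())}
    if reference is None:
        reference = max(rows, key=lambda n: rows[n]["elpd_loo"])
    for name in rows:
        d, (lo, hi) = elpd_diff(point[name], point[reference])
        rows[name]["elpd_diff"] = d
        rows[name]["elpd_diff_ci_low"] = lo
        rows[name]["elpd_diff_ci_high"] = hi
    out = pd.DataFrame(rows).T
    out.index.name = "model"
    return out.sort_values("elpd_loo", ascending=False)


def arcsine_sqrt(prop) -> np.ndarray | float:
    """Variance-stabilizing transform of a proportion: asin(sqrt(p))."""
    p = np.asarray(prop, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def _subject_drift(row: pd.Series | dict, sv_diff: np.ndarray, variant: str) -> np.ndarray:
    row = dict(row)
    if variant == "ddm0":
        return np.full(len(sv_diff), row["v"])
    if variant == "ddmlin":
        return row["v_coeff"] * sv_diff
    if variant in ("ddms", "mixture"):
        return drift_sigmoid(sv_diff, row["v_coeff"], row["v_max"])
    raise ValueError(f"unknown DDM variant {variant!r}")


def predict_choices(subject_params: pd.Series | dict, trials: pd.DataFrame,
                    variant: str) -> tuple[np.ndarray, float]:
    """Deterministic choice predictions from mean-posterior parameters.

    DDM variants predict the upper boundary iff its absorption probability
    exceeds .5 (ties go to the upper boundary by convention); the softmax
    variant thresholds the choice probability the same way.  Returns the
    predicted boundaries and, when ``trials`` carries an observed
    ``boundary`` column, the prediction accuracy (else NaN).
    """
    from .value_models import sv_difference
    row = dict(subject_params)
    svd = sv_difference(trials, row.get("log_k_now", 0.0),
                        row.get("shift_logk", 0.0), row.get("log_h", 0.0))
    if variant == "softmax":
        from .ddm_core import softmax_p_choice
        p_up = np.atleast_1d(softmax_p_choice(svd, 0.0, row["beta"]))
    else:
        drift = _subject_drift(row, svd, variant)
        params = DDMParams(row["alpha"], row["tau"], row["z"]).validate()
        p_up = np.array([p_upper(params, v) for v in drift])
    pred = np.where(p_up >= 0.5, "upper", "lower")
    acc = np.nan
    if "boundary" in trials.columns:
        acc = float((pred == trials["boundary"].to_numpy()).mean())
    return pred, acc


def prediction_accuracies(post: PosteriorSamples, data: pd.DataFrame) -> pd.DataFrame:
    """Per-subject accuracy of mean-posterior choice predictions."""
    means = post.subject_posterior_means()
    rows = []
    for _, row in means.iterrows():
        sub = data[data["subject_id"] == row["subject_id"]]
        _, acc = predict_choices(row, sub, post.spec.variant)
        rows.append((row["subject_id"], row["group"], acc))
    return pd.DataFrame(rows, columns=["subject_id", "group", "accuracy"])


def value_bin_rts(data: pd.DataFrame, svs: np.ndarray, n_bins: int = 5) -> pd.DataFrame:
    """Equal-count value bins per subject: mean |RT| and mean SV per bin.

    ``svs`` is aligned with ``data`` rows (subjective value of the LL/risky
    option).  Bin counts differ by at most one; ties broken by row order.
    A subject whose SVs are all equal is flagged ``degenerate``.
    """
    df = data.copy()
    df["_sv"] = np.asarray(svs, float)
    rows = []
    for sid, g in df.groupby("subject_id", sort=False):
        if len(g) < n_bins:
            raise ValueError(f"subject {sid} has fewer trials than bins")
        order = np.argsort(g["_sv"].to_numpy(), kind="stable")
        degenerate = bool(np.ptp(g["_sv"].to_numpy()) == 0)
        for b, idx in enumerate(np.array_split(order, n_bins)):
            sub = g.iloc[idx]
            rows.append((sid, b, float(sub["_sv"].mean()),
                         float(sub["rt"].abs().mean()), len(idx), degenerate))
    return pd.DataFrame(rows, columns=["subject_id", "bin", "sv_mean",
                                       "rt_mean", "n", "degenerate"])


@dataclass
class PPCBundle:
    """Posterior predictive simulations and the value-bin RT table."""

    bin_table: pd.DataFrame      # per subject x bin: observed & predicted mean RT
    pred_rts: dict               # subject_id -> pooled predicted |rt| sample
    n_sim: int

    def density(self, subject_id: str):
        """Silverman-bandwidth Gaussian KDE of a subject's predicted RTs."""
        return gaussian_kde(self.pred_rts[subject_id], bw_method="silverman")


def ppc_simulate(post: PosteriorSamples, data: pd.DataFrame, n_sim: int = 1000,
                 seed: int = 0, n_bins: int = 5,
                 max_stored_rts: int = 2000) -> PPCBundle:
    """Simulate full datasets from the fitted posterior and bin them by value.

    For each simulation a joint posterior draw is selected and a full dataset
    is simulated per subject with that draw's subject-level parameters; the
    value bins are fixed by the observed trials' subjective values at each
    subject's mean-posterior discounting parameters, so observed and
    predicted mean RTs are compared on the same bins.
    """
    from .value_models import sv_difference
    rng = np.random.default_rng(seed)
    variant = post.spec.variant
    means = post.subject_posterior_means().set_index("subject_id")
    n_chains, n_draws = post.subject.shape[:2]

    obs_bins = {}
    svd_mean = {}
    trial_tables = {}
    for sid in post.subject_ids:
        sub = data[data["subject_id"] == sid]
        trial_tables[sid] = sub
        row = means.loc[sid]
        svd = sv_difference(sub, row.get("log_k_now", 0.0),
                            row.get("shift_logk", 0.0), row.get("log_h", 0.0))
        svd_mean[sid] = svd
        sv_option = svd + (sub["amount_ss"] if "amount_ss" in sub.columns
                           else sub["amount_safe"]).to_numpy(float)
        order = np.argsort(sv_option, kind="stable")
        obs_bins[sid] = np.array_split(order, n_bins)

    pred_sum = {sid: np.zeros(n_bins) for sid in post.subject_ids}
    pred_cnt = {sid: np.zeros(n_bins) for sid in post.subject_ids}
    pooled = {sid: [] for sid in post.subject_ids}
    for sim in range(n_sim):
        c = rng.integers(n_chains)
        d = rng.integers(n_draws)
        for s, sid in enumerate(post.subject_ids):
            row = pd.Series(post.subject[c, d, s], index=post.param_names)
            sub = trial_tables[sid]
            svd = sv_difference(sub, row.get("log_k_now", 0.0),
                                row.get("shift_logk", 0.0), row.get("log_h", 0.0))
            drift = _subject_drift(row, svd, variant)
            params = DDMParams(row["alpha"], row["tau"], row["z"])
            sim_df = simulate_trials(params, drift, seed=int(rng.integers(2**31)))
            rts = sim_df["rt"].to_numpy()
            ok = ~sim_df["censored"].to_numpy()
            for b, idx in enumerate(obs_bins[sid]):
                sel = ok[idx]
                if sel.any():
                    pred_sum[sid][b] += rts[idx][sel].sum()
                    pred_cnt[sid][b] += sel.sum()
            pooled[sid].append(rts[ok])

    rows = []
    for sid in post.subject_ids:
        sub = trial_tables[sid]
        obs_rt = sub["rt"].abs().to_numpy()
        sv_option = svd_mean[sid] + (sub["amount_ss"] if "amount_ss" in sub.columns
                                     else sub["amount_safe"]).to_numpy(float)
        for b, idx in enumerate(obs_bins[sid]):
            pred = pred_sum[sid][b] / max(pred_cnt[sid][b], 1)
            rows.append((sid, b, float(sv_option[idx].mean()),
                         float(obs_rt[idx].mean()), float(pred)))
    bin_table = pd.DataFrame(rows, columns=["subject_id", "bin", "sv_mean",
                                            "rt_obs_mean", "rt_pred_mean"])
    pred_rts = {}
    for sid in post.subject_ids:
        arr = np.concatenate(pooled[sid]) if pooled[sid] else np.empty(0)
        if arr.size > max_stored_rts:
            arr = rng.choice(arr, max_stored_rts, replace=False)
        pred_rts[sid] = arr
    return PPCBundle(bin_table=bin_table, pred_rts=pred_rts, n_sim=n_sim)
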