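"""Group-difference statistics, drift-component simulation studies and the
parameter-recovery harness.

Group differences are always patients minus controls.  Directional Bayes
factors follow BF = i / (1 - i) with i the kernel-density mass of the
difference posterior above zero; BF > 3 counts as positive and BF > 12 as
strong evidence for an increase, BF < 1/3 as evidence for a reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .ddm_core import DDMParams, simulate_trials, trim_rts
from .inference import MCMCConfig, PosteriorSamples, build_model, fit_hierarchical
from .synthetic_cohort import CohortConfig, generate_cohort

BF_POSITIVE = 3.0
BF_STRONG = 12.0
BF_NEGATIVE = 1.0 / 3.0
BF_CAP = 1000.0

#: fixed diffusion parameters of the drift-component simulations
#: (control-group posterior means)
SIM_FIXED = {"alpha": 3.37, "tau": 0.945, "z": 0.531}
SIM_V_MAX_GRID = (0.5, 1.0, 1.5, 2.5, 3.5)
SIM_V_COEFF_GRID = (0.05, 0.1, 0.2, 0.4, 1.0, 2.0)


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, float).ravel())
    if x.size < 100:
        raise ValueError("hdi requires at least 100 draws")
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    m = int(np.ceil(mass * x.size))
    widths = x[m - 1:] - x[:x.size - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def directional_bf(diff_draws: np.ndarray, cap: float = BF_CAP) -> float:
    """Directional Bayes factor i/(1-i), i = smoothed posterior mass above 0.

    The mass is estimated from a Silverman-bandwidth Gaussian KDE of the
    difference draws; the ratio is capped at ``cap`` (and 1/cap).
    """
    x = np.asarray(diff_draws, float).ravel()
    if x.size < 1000:
        raise ValueError("directional_bf requires at least 1000 draws")
    if np.ptp(x) == 0:
        raise ValueError("degenerate difference distribution")
    kde = gaussian_kde(x, bw_method="silverman")
    i = float(np.clip(kde.integrate_box_1d(0.0, np.inf), 0.0, 1.0))
    if i >= 1.0:
        return cap
    bf = i / (1.0 - i)
    return float(np.clip(bf, 1.0 / cap, cap))


def cohens_d(mu1_draws, mu2_draws, prec1_draws, prec2_draws) -> float:
    """Standardized group difference from group-level posteriors.

    (posterior-mean group mean 1 - group mean 2) divided by the pooled SD
    derived from the posterior-mean precisions; groups weighted equally.
    """
    p1 = float(np.mean(prec1_draws))
    p2 = float(np.mean(prec2_draws))
    if p1 <= 0 or p2 <= 0:
        raise ValueError("precisions must be positive")
    sd_pooled = np.sqrt((1.0 / p1 + 1.0 / p2) / 2.0)
    return float((np.mean(mu1_draws) - np.mean(mu2_draws)) / sd_pooled)


def difference_stats(mu1_draws, mu2_draws, prec1_draws, prec2_draws) -> dict:
    """Group-1-minus-group-2 statistics from group-level posterior draws:
    mean difference, 85%/95% HDIs, directional BF and Cohen's d."""
    diff = np.asarray(mu1_draws, float).ravel() - np.asarray(mu2_draws, float).ravel()
    h85 = hdi(diff, 0.85)
    h95 = hdi(diff, 0.95)
    return {
        "m_diff": float(diff.mean()),
        "hdi85_low": h85[0], "hdi85_high": h85[1],
        "hdi95_low": h95[0], "hdi95_high": h95[1],
        "bf": directional_bf(diff),
        "d": cohens_d(mu1_draws, mu2_draws, prec1_draws, prec2_draws),
    }


def group_difference_report(post: PosteriorSamples) -> pd.DataFrame:
    """Per-parameter patients-minus-controls difference statistics:
    M_diff, 85%/95% HDIs, directional BF and Cohen's d."""
    if set(post.groups_present) != {"patients", "controls"}:
        raise ValueError("report requires both groups in the posterior")
    rows = []
    for name in post.param_names:
        stats = difference_stats(
            post.group_mean(name, "patients").ravel(),
            post.group_mean(name, "controls").ravel(),
            1.0 / post.group_sd(name, "patients").ravel() ** 2,
            1.0 / post.group_sd(name, "controls").ravel() ** 2)
        rows.append({"parameter": name, **stats})
    return pd.DataFrame(rows)


def drift_grid_simulation(
    v_max_grid=SIM_V_MAX_GRID,
    v_coeff_grid=SIM_V_COEFF_GRID,
    fixed: dict | None = None,
    n_rt: int = 50,
    value_diffs: np.ndarray | None = None,
    n_bins: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """RT/choice behaviour of the sigmoid-drift DDM over a drift-component grid.

    For every (v_max, v_coeff) cell, ``n_rt`` trials are simulated at each of
    the value differences (default: 400 points spanning -20..+20) with the
    other diffusion parameters fixed at the control posterior means; the
    summary holds mean RT and upper-boundary proportion per value-difference
    bin and cell.
    """
    from .ddm_core import drift_sigmoid
    v_max_grid = list(v_max_grid)
    v_coeff_grid = list(v_coeff_grid)
    if not v_max_grid or not v_coeff_grid:
        raise ValueError("empty simulation grid")
    fixed = {**SIM_FIXED, **(fixed or {})}
    if value_diffs is None:
        value_diffs = np.linspace(-20.0, 20.0, 400)
    value_diffs = np.asarray(value_diffs, float)

    edges = np.linspace(value_diffs.min(), value_diffs.max(), n_bins + 1)
    rows = []
    rng = np.random.default_rng(seed)
    for vm in v_max_grid:
        for vc in v_coeff_grid:
            drift = np.repeat(drift_sigmoid(value_diffs, vc, vm), n_rt)
            vd = np.repeat(value_diffs, n_rt)
            params = DDMParams(fixed["alpha"], fixed["tau"], fixed["z"])
            sim = simulate_trials(params, drift, seed=int(rng.integers(2**31)))
            ok = ~sim["censored"].to_numpy()
            rt = sim["rt"].to_numpy()
            upper = (sim["boundary"] == "upper").to_numpy()
            which = np.clip(np.digitize(vd, edges) - 1, 0, n_bins - 1)
            for b in range(n_bins):
                sel = (which == b) & ok
                if not sel.any():
                    continue
                rows.append((vm, vc, b, float(vd[sel].mean()),
                             float(rt[sel].mean()), float(upper[sel].mean()),
                             int(sel.sum())))
    return pd.DataFrame(rows, columns=["v_max", "v_coeff", "bin", "value_diff",
                                       "mean_rt", "p_upper", "n"])


@dataclass
class RecoveryReport:
    """Recovery of group-level means (HDI coverage) and subject-level
    parameters (true vs posterior-mean scatter) over refitted datasets."""

    group_table: pd.DataFrame     # dataset, group, parameter, true, mean, hdi, covered
    subject_table: pd.DataFrame   # dataset, subject, parameter, true, estimate

    def coverage(self) -> float:
        return float(self.group_table["covered"].mean())

    def subject_correlations(self) -> pd.Series:
        return self.subject_table.groupby("parameter")[["true", "estimate"]].corr() \
            .iloc[0::2]["estimate"].droplevel(1)


def parameter_recovery(
    config: CohortConfig | None = None,
    n_datasets: int = 10,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    trim_fraction: float = 0.025,
) -> RecoveryReport:
    """Simulate datasets from known group-level truths and refit them with
    the generating (sigmoid-drift) model.

    Each dataset draws fresh subjects from the configured group-level
    distributions, generates their data, trims RTs and refits; the report
    records whether each group-level 95% HDI covers the true group mean and
    pairs every subject's true parameters with the posterior means.
    """
    config = config or CohortConfig()
    spec = build_model(config.task, config.variant)
    group_rows, subject_rows = [], []
    for ds in range(n_datasets):
        bundle = generate_cohort(config, seed=int((seed * 1009 + ds) % 2**31))
        data = trim_rts(bundle.merged(), trim_fraction)
        post = fit_hierarchical(data, spec, mcmc, seed=int((seed * 1013 + ds) % 2**31))
        max_rhat = float(post.rhat()["rhat"].max())
        for g in post.groups_present:
            true_means = bundle.config.hyper[g].means
            for name in spec.params:
                draws = post.group_mean(name, g).ravel()
                lo, hi = hdi(draws, 0.95)
                true = float(true_means[name])
                group_rows.append((ds, g, name, true, float(draws.mean()),
                                   lo, hi, bool(lo <= true <= hi), max_rhat))
        est = post.subject_posterior_means().set_index("subject_id")
        truth = bundle.truth.set_index("subject_id")
        for sid in est.index:
            for name in spec.params:
                subject_rows.append((ds, sid, name, float(truth.loc[sid, name]),
                                     float(est.loc[sid, name])))
    return RecoveryReport(
        group_table=pd.DataFrame(group_rows, columns=[
            "dataset", "group", "parameter", "true", "post_mean",
            "hdi_low", "hdi_high", "covered", "max_rhat"]),
        subject_table=pd.DataFrame(subject_rows, columns=[
            "dataset", "subject_id", "parameter", "true", "estimate"]),
    )
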