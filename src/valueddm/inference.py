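"""Hierarchical Bayesian estimation of the choice-rule models by MCMC.

The generative model: for each group (patients, controls) and each subject
parameter, a group-level mean (uniform prior over the domain bounds; a
Gaussian(0, 2) prior for the log(k) shift) and a group-level precision
(gamma(.001, .001) prior); subject parameters are normal around their
group's mean with that precision, truncated to the domain bounds; trials are
Bernoulli (softmax) or Wiener first-passage (DDM variants) given the subject
parameters, with the mixture variant marginalizing a per-trial latent
component indicator: lambda * f_sigmoid + (1 - lambda) * f_null.

Sampling uses an adaptive Metropolis-within-Gibbs scheme (see _sampler);
the estimation contract is the prior table, the exact likelihood, split-R̂
diagnostics and seed determinism, not any particular sampler brand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _sampler
from ._params import (PARAM_TABLE, PRECISION_PRIOR_RATE, PRECISION_PRIOR_SHAPE,
                      SHIFT_PRIOR_SD, TASKS, VARIANTS, bounds_arrays,
                      param_names)

GROUPS = ("patients", "controls")
_VARIANT_CODE = {v: i for i, v in enumerate(VARIANTS)}
_TASK_CODE = {t: i for i, t in enumerate(TASKS)}

# weakly informative interior starting points for group means; non-decision
# time is additionally capped below each subject's fastest trial
_INIT_MEANS = {
    "alpha": 2.5, "tau": 0.8, "z": 0.5, "v_coeff": 0.1, "v_max": 1.0,
    "v": 0.0, "log_k_now": -4.0, "shift_logk": 0.0, "log_h": 0.0,
    "lambda_z": 0.0, "beta": 0.5,
    "alpha_0": 2.5, "tau_0": 0.8, "z_0": 0.5, "v_0": 0.0,
}


@dataclass(frozen=True)
class ModelSpec:
    """A (task, variant) model: parameter list, domains and priors."""

    task: str
    variant: str
    params: tuple[str, ...]

    @property
    def prior_table(self) -> pd.DataFrame:
        rows = []
        for name in self.params:
            lo, hi, kind = PARAM_TABLE[name]
            mean_prior = (f"Normal(0, {SHIFT_PRIOR_SD})" if kind == "normal"
                          else f"Uniform({lo}, {hi})")
            rows.append((name, lo, hi, mean_prior,
                         f"Gamma({PRECISION_PRIOR_SHAPE}, {PRECISION_PRIOR_RATE})"))
        return pd.DataFrame(rows, columns=["parameter", "lower", "upper",
                                           "group_mean_prior", "group_precision_prior"])


def build_model(task: str, variant: str) -> ModelSpec:
    """Model specification for a task/variant combination."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    return ModelSpec(task, variant, tuple(param_names(task, variant)))


@dataclass
class MCMCConfig:
    """Sampler settings.  The desk default (2 chains, 2000 warm-up, 2000
    retained) is sized for synthetic cohorts; ``paper()`` gives the original
    large-scale settings (2 chains, 50k burn-in, thinning 2, 10k retained)."""

    chains: int = 2
    warmup: int = 2000
    draws: int = 2000
    thin: int = 1

    @classmethod
    def paper(cls) -> "MCMCConfig":
        return cls(chains=2, warmup=50_000, draws=10_000, thin=2)


def _prepare_data(data: pd.DataFrame, task: str) -> dict:
    """Flatten a long trial table into the sampler's contiguous arrays."""
    df = data.copy()
    if "censored" in df.columns:
        df = df[~df["censored"].astype(bool)]
    if "group" not in df.columns:
        raise ValueError("data must carry a 'group' column")
    df["_gcode"] = df["group"].map({g: i for i, g in enumerate(GROUPS)})
    if df["_gcode"].isna().any():
        bad = sorted(set(df["group"]) - set(GROUPS))
        raise ValueError(f"unknown group labels {bad}")
    df = df.sort_values(["_gcode", "subject_id"], kind="stable")

    if task == "TD":
        amount = df["amount_ll"].to_numpy(float)
        ref = df["amount_ss"].to_numpy(float)
        x1 = df["iri"].to_numpy(float)
        x2 = df["condition_I"].to_numpy(float)
    else:
        amount = df["amount_risky"].to_numpy(float)
        ref = df["amount_safe"].to_numpy(float)
        p = df["probability"].to_numpy(float)
        x1 = (1.0 - p) / p
        x2 = np.zeros(len(df))

    subj_ids, counts = [], []
    for sid, g in df.groupby("subject_id", sort=False):
        subj_ids.append(sid)
        counts.append(len(g))
    subj_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    group = df.groupby("subject_id", sort=False)["_gcode"].first().to_numpy(np.int64)
    srt = df["signed_rt"].to_numpy(float)
    min_rt = np.array([np.abs(srt[subj_ptr[s]:subj_ptr[s + 1]]).min()
                       for s in range(len(subj_ids))])
    return {
        "srt": np.ascontiguousarray(srt),
        "amount": np.ascontiguousarray(amount),
        "ref": np.ascontiguousarray(ref),
        "x1": np.ascontiguousarray(x1),
        "x2": np.ascontiguousarray(x2),
        "subj_ptr": subj_ptr,
        "group": group,
        "subject_ids": subj_ids,
        "min_rt": min_rt,
    }


@dataclass
class PosteriorSamples:
    """Labelled MCMC draws: group means/SDs and subject-level parameters.

    Array shapes: ``mu``/``log_sd`` (chains, draws, group, param),
    ``subject`` (chains, draws, subject, param).
    """

    spec: ModelSpec
    mu: np.ndarray
    log_sd: np.ndarray
    subject: np.ndarray
    param_names: list[str]
    subject_ids: list[str]
    subject_groups: np.ndarray      # group code per subject
    meta: dict = field(default_factory=dict)
    data: dict | None = None        # prepared arrays, kept for log-lik reuse

    # --- accessors -------------------------------------------------------
    def _pindex(self, name: str) -> int:
        return self.param_names.index(name)

    def group_mean(self, name: str, group: str) -> np.ndarray:
        """(chains, draws) draws of one group-level mean."""
        return self.mu[:, :, GROUPS.index(group), self._pindex(name)]

    def group_sd(self, name: str, group: str) -> np.ndarray:
        return np.exp(self.log_sd[:, :, GROUPS.index(group), self._pindex(name)])

    def subject_draws(self, name: str) -> np.ndarray:
        """(chains, draws, subjects) draws of one subject-level parameter."""
        return self.subject[:, :, :, self._pindex(name)]

    def subject_posterior_means(self) -> pd.DataFrame:
        means = self.subject.mean(axis=(0, 1))
        df = pd.DataFrame(means, columns=self.param_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", [GROUPS[g] for g in self.subject_groups])
        return df

    @property
    def groups_present(self) -> list[str]:
        return [g for i, g in enumerate(GROUPS) if (self.subject_groups == i).any()]

    # --- diagnostics -----------------------------------------------------
    def rhat(self) -> pd.DataFrame:
        """Split-R̂ for every group-level and subject-level parameter."""
        rows = []
        for j, name in enumerate(self.param_names):
            for g in self.groups_present:
                gi = GROUPS.index(g)
                rows.append((f"mu[{g},{name}]", rhat(self.mu[:, :, gi, j])))
                rows.append((f"sd[{g},{name}]", rhat(self.log_sd[:, :, gi, j])))
            for s, sid in enumerate(self.subject_ids):
                rows.append((f"{name}[{sid}]", rhat(self.subject[:, :, s, j])))
        return pd.DataFrame(rows, columns=["parameter", "rhat"])

    def pointwise_loglik(self, max_draws: int | None = None) -> np.ndarray:
        """(total draws, n_trials) conditional log-likelihood matrix."""
        if self.data is None:
            raise ValueError("posterior carries no data arrays")
        th = self.subject.reshape(-1, *self.subject.shape[2:])
        if max_draws is not None and th.shape[0] > max_draws:
            idx = np.linspace(0, th.shape[0] - 1, max_draws).astype(int)
            th = th[idx]
        d = self.data
        return _sampler.pointwise_loglik(
            _VARIANT_CODE[self.spec.variant], _TASK_CODE[self.spec.task],
            np.ascontiguousarray(th), d["srt"], d["amount"], d["ref"],
            d["x1"], d["x2"], d["subj_ptr"])

    # --- serialization ---------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        extra = {}
        if self.data is not None:
            extra = {k: v for k, v in self.data.items() if isinstance(v, np.ndarray)}
        np.savez(path / "draws.npz", mu=self.mu, log_sd=self.log_sd,
                 subject=self.subject, subject_groups=self.subject_groups,
                 **extra)
        meta = {"task": self.spec.task, "variant": self.spec.variant,
                "param_names": list(self.param_names),
                "subject_ids": list(self.subject_ids), "meta": self.meta,
                "has_data": self.data is not None}
        (path / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        arrs = np.load(path / "draws.npz")
        data = None
        if meta["has_data"]:
            data = {k: arrs[k] for k in
                    ("srt", "amount", "ref", "x1", "x2", "subj_ptr", "group", "min_rt")}
            data["subject_ids"] = meta["subject_ids"]
        return cls(build_model(meta["task"], meta["variant"]),
                   arrs["mu"], arrs["log_sd"], arrs["subject"],
                   meta["param_names"], meta["subject_ids"],
                   arrs["subject_groups"], meta["meta"], data)


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential-scale-reduction statistic.

    ``draws`` has shape (chains, iterations); each chain is split in half, so
    R̂ detects both between-chain disagreement and within-chain drift.
    Identical constant chains give exactly 1.
    """
    draws = np.asarray(draws, float)
    if draws.ndim != 2:
        raise ValueError("draws must be (chains, iterations)")
    m, n = draws.shape
    if m < 2:
        raise ValueError("rhat requires at least two chains")
    half = n // 2
    split = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    b = half * split.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else float(np.inf)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def log_likelihood(data: pd.DataFrame, params: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Per-trial log-likelihood vector at fixed subject parameters.

    ``params``: one row per subject with a column per model parameter (extra
    columns ignored, subjects matched by subject_id when present); trials
    with |rt| <= tau contribute -inf, not an error.
    """
    d = _prepare_data(data, spec.task)
    if "subject_id" in getattr(params, "columns", []):
        params = params.set_index("subject_id")
    theta = np.empty((1, len(d["subject_ids"]), len(spec.params)))
    for s, sid in enumerate(d["subject_ids"]):
        row = params.loc[sid] if sid in params.index else params.iloc[s]
        theta[0, s] = [float(row[p]) for p in spec.params]
    out = _sampler.pointwise_loglik(
        _VARIANT_CODE[spec.variant], _TASK_CODE[spec.task],
        np.ascontiguousarray(theta), d["srt"], d["amount"], d["ref"],
        d["x1"], d["x2"], d["subj_ptr"])
    return out[0]


def fit_hierarchical(
    data: pd.DataFrame,
    spec: ModelSpec,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorSamples:
    """Fit the hierarchical model to a (trimmed) long trial table.

    ``data`` needs subject_id, group, signed_rt and the task's design
    columns.  Each group present gets its own group-level distributions;
    identical seed and config give identical draws.
    """
    mcmc = mcmc or MCMCConfig()
    d = _prepare_data(data, spec.task)
    names = list(spec.params)
    lo, hi, prior_normal = bounds_arrays(names)
    n_s, n_p = len(d["subject_ids"]), len(names)

    for g in set(d["group"]):
        if (d["group"] == g).sum() < 2:
            raise ValueError(f"group {GROUPS[g]!r} has fewer than 2 subjects")
    # a subject whose fastest trial sits at the non-decision floor admits no
    # finite-likelihood tau; diagnose it up front with the subject named
    tau_floor = PARAM_TABLE["tau"][0] + 2e-3
    if spec.variant != "softmax" and np.any(d["min_rt"] <= tau_floor):
        bad = [d["subject_ids"][i]
               for i in np.nonzero(d["min_rt"] <= tau_floor)[0]]
        raise ValueError(
            f"subjects with RTs at or below the non-decision floor: {bad}")

    mu_all, ls_all, th_all = [], [], []
    for chain in range(mcmc.chains):
        rng = np.random.default_rng([seed, chain])
        mu0 = np.empty((2, n_p))
        ls0 = np.full((2, n_p), np.log(0.3))
        for j, name in enumerate(names):
            base = _INIT_MEANS[name]
            mu0[:, j] = np.clip(base + 0.05 * rng.standard_normal(2),
                                lo[j] + 1e-6, hi[j] - 1e-6)
        th0 = np.empty((n_s, n_p))
        for s in range(n_s):
            g = d["group"][s]
            th0[s] = np.clip(mu0[g] + 0.02 * rng.standard_normal(n_p),
                             lo + 1e-6, hi - 1e-6)
        for j, name in enumerate(names):
            if name.startswith("tau"):
                tcap = np.clip(0.85 * d["min_rt"], tau_floor + 1e-3, None)
                th0[:, j] = np.minimum(th0[:, j], tcap)
                for g in (0, 1):
                    sel = d["group"] == g
                    if sel.any():
                        mu0[g, j] = th0[sel, j].mean()

        chain_seed = int((seed * 100003 + 7919 * chain + 1) % (2**31))
        mu_d, ls_d, th_d = _sampler.run_chain(
            _VARIANT_CODE[spec.variant], _TASK_CODE[spec.task],
            d["srt"], d["amount"], d["ref"], d["x1"], d["x2"],
            d["subj_ptr"], d["group"], lo, hi, prior_normal,
            SHIFT_PRIOR_SD, PRECISION_PRIOR_SHAPE, PRECISION_PRIOR_RATE,
            mu0, ls0, th0, mcmc.warmup, mcmc.draws, mcmc.thin, chain_seed)
        mu_all.append(mu_d)
        ls_all.append(ls_d)
        th_all.append(th_d)

    post = PosteriorSamples(
        spec=spec,
        mu=np.stack(mu_all).transpose(0, 1, 2, 3),
        log_sd=np.stack(ls_all),
        subject=np.stack(th_all),
        param_names=names,
        subject_ids=d["subject_ids"],
        subject_groups=d["group"],
        meta={"seed": seed, "chains": mcmc.chains, "warmup": mcmc.warmup,
              "draws": mcmc.draws, "thin": mcmc.thin},
        data=d,
    )
    if not np.isfinite(post.mu).all() or not np.isfinite(post.subject).all():
        raise RuntimeError("sampler produced non-finite draws")
    return post
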