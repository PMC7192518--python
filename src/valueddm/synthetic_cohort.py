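"""Synthetic two-group study cohorts with the hierarchical structure the
analysis assumes.

Subject-level parameters are drawn from group-level truncated normal
distributions (truncation at the domain bounds); choices and response times
are then generated trial-by-trial through the diffusion simulator, so every
downstream stage — estimation, model comparison, predictive checks, recovery
— can be exercised without any external data.

The default study conditions are 9 "patients" and 19 "controls"; control
group means for boundary separation (3.37), non-decision time (.945 s) and
start bias (.531) follow the reported control-group posteriors, and the
default patient group differs in non-decision time (+.184 s) and in the
log(k) shift (+.529), matching the sign and size of the reported group
effects.  Remaining means and the between-subject spreads are package
defaults chosen to give realistic choice/RT behaviour on these task grids;
see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from ._params import PARAM_TABLE
from ._sampler import _phi  # inverse-probit lives next to the likelihoods
from . import task_designs
from .ddm_core import DDMParams, simulate_trials
from .value_models import sv_difference

GROUPS = ("patients", "controls")

_CONTROL_MEANS = {
    "alpha": 3.37, "tau": 0.945, "z": 0.531,
    "v_coeff": 0.5, "v_max": 1.5, "v": 0.0,
    "log_k_now": -3.5, "shift_logk": 1.0, "log_h": 0.5,
    "lambda_z": 4.0, "beta": 0.3,
    "alpha_0": 3.37, "tau_0": 0.945, "z_0": 0.531, "v_0": 0.0,
}
_CONTROL_SDS = {
    "alpha": 0.5, "tau": 0.15, "z": 0.05,
    "v_coeff": 0.15, "v_max": 0.3, "v": 0.3,
    "log_k_now": 1.5, "shift_logk": 0.5, "log_h": 1.0,
    "lambda_z": 1.0, "beta": 0.1,
    "alpha_0": 0.5, "tau_0": 0.15, "z_0": 0.05, "v_0": 0.3,
}
#: default patient-minus-control shifts in group means (non-decision time and
#: log(k) shift, signs per the reported group effects)
_PATIENT_OFFSETS = {"tau": 0.184, "tau_0": 0.184, "shift_logk": 0.529}


@dataclass
class GroupHyper:
    """Group-level mean and precision (1/variance) of each subject parameter."""

    means: dict[str, float]
    precisions: dict[str, float]

    @property
    def sds(self) -> dict[str, float]:
        return {k: 1.0 / np.sqrt(v) for k, v in self.precisions.items()}

    def validate(self) -> "GroupHyper":
        for name, prec in self.precisions.items():
            if not prec > 0:
                raise ValueError(f"precision of {name} must be positive")
        for name, mean in self.means.items():
            lo, hi, _ = PARAM_TABLE[name]
            if not lo <= mean <= hi:
                raise ValueError(f"group mean of {name} outside its domain [{lo}, {hi}]")
        return self

    @classmethod
    def default_controls(cls) -> "GroupHyper":
        return cls(dict(_CONTROL_MEANS),
                   {k: 1.0 / v**2 for k, v in _CONTROL_SDS.items()})

    @classmethod
    def default_patients(cls) -> "GroupHyper":
        h = cls.default_controls()
        for name, off in _PATIENT_OFFSETS.items():
            h.means[name] += off
        return h


def sample_subject_params(hyper: GroupHyper, n_subjects: int, seed: int) -> pd.DataFrame:
    """Truncated-normal subject draws around the group means (one row each)."""
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    hyper.validate()
    rng = np.random.default_rng(seed)
    cols = {}
    for name in hyper.means:
        lo, hi, _ = PARAM_TABLE[name]
        mu = hyper.means[name]
        sd = hyper.sds[name]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        cols[name] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n_subjects,
                                   random_state=rng)
    return pd.DataFrame(cols)


def lambda_mix(lambda_z: float) -> float:
    """Inverse-probit map of the mixture coordinate to a proportion in [0, 1]."""
    return float(_phi(float(lambda_z)))


def _reduced_td_amounts():
    return (10.2, 11.0, 15.0, 20.0, 40.0, 100.0, 150.0)


def _reduced_pd_amounts():
    return (10.2, 11.0, 15.0, 20.0, 30.0, 50.0, 100.0, 150.0)


def make_design(task: str, size: str = "full") -> pd.DataFrame:
    """Task trial grid; ``size='reduced'`` gives the 56-trial desk grids."""
    if task == "TD":
        if size == "reduced":
            return task_designs.generate_td_design(
                amounts=_reduced_td_amounts(), delays=(1, 5, 14, 60))
        return task_designs.generate_td_design()
    if task == "PD":
        if size == "reduced":
            return task_designs.generate_pd_design(amounts=_reduced_pd_amounts())
        return task_designs.generate_pd_design()
    raise ValueError(f"unknown task {task!r}")


def generate_dataset(
    design: pd.DataFrame,
    subject: dict | pd.Series,
    variant: str,
    seed: int,
    dt: float = 0.001,
    max_time: float = 30.0,
) -> pd.DataFrame:
    """Choices and RTs for one subject over a trial grid.

    ``variant`` selects the generative choice rule: "ddm0" (constant drift),
    "ddmlin" (linear drift), "ddms" (sigmoid drift), "mixture" (per-trial
    latent indicator with probability inverse-probit(lambda_z) of the sigmoid
    component) or "softmax" (binary choices only, rt set to NaN).
    """
    subject = dict(subject)
    rng = np.random.default_rng(seed)
    svd = sv_difference(
        design,
        log_k_now=subject.get("log_k_now", 0.0),
        shift_logk=subject.get("shift_logk", 0.0),
        log_h=subject.get("log_h", 0.0),
    )

    if variant == "softmax":
        from .ddm_core import softmax_p_choice
        p_up = softmax_p_choice(svd, 0.0, subject["beta"])
        upper = rng.random(len(design)) < p_up
        return pd.DataFrame({
            "trial_index": design["trial_index"].to_numpy(),
            "boundary": np.where(upper, "upper", "lower"),
            "rt": np.nan,
            "censored": False,
            "signed_rt": np.where(upper, 1.0, -1.0),
        })

    if variant == "ddm0":
        drift = np.full(len(design), subject["v"])
    elif variant == "ddmlin":
        drift = subject["v_coeff"] * svd
    elif variant in ("ddms", "mixture"):
        from .ddm_core import drift_sigmoid
        drift = drift_sigmoid(svd, subject["v_coeff"], subject["v_max"])
    else:
        raise ValueError(f"unknown variant {variant!r}")

    params = DDMParams(subject["alpha"], subject["tau"], subject["z"],
                       subject.get("v_coeff", 0.0), subject.get("v_max", 1.0))
    if variant != "mixture":
        out = simulate_trials(params, drift, seed=int(rng.integers(2**31)),
                              dt=dt, max_time=max_time)
        out["trial_index"] = design["trial_index"].to_numpy()
        return out

    # mixture: per-trial component indicator, each component with its own
    # full diffusion parameter set
    lam = lambda_mix(subject["lambda_z"])
    use_s = rng.random(len(design)) < lam
    params0 = DDMParams(subject["alpha_0"], subject["tau_0"], subject["z_0"])
    parts = []
    if use_s.any():
        sim = simulate_trials(params, drift[use_s], seed=int(rng.integers(2**31)),
                              dt=dt, max_time=max_time)
        sim["trial_index"] = design["trial_index"].to_numpy()[use_s]
        parts.append(sim)
    if (~use_s).any():
        v0 = np.full(int((~use_s).sum()), subject["v_0"])
        sim = simulate_trials(params0, v0, seed=int(rng.integers(2**31)),
                              dt=dt, max_time=max_time)
        sim["trial_index"] = design["trial_index"].to_numpy()[~use_s]
        parts.append(sim)
    out = pd.concat(parts).sort_values("trial_index").reset_index(drop=True)
    return out


@dataclass
class CohortConfig:
    """Study-generation settings; defaults are the study conditions."""

    task: str = "TD"
    variant: str = "ddms"
    n_patients: int = 9
    n_controls: int = 19
    design_size: str = "full"  # or "reduced" (56-trial desk grid)
    hyper: dict[str, GroupHyper] = field(default_factory=lambda: {
        "patients": GroupHyper.default_patients(),
        "controls": GroupHyper.default_controls(),
    })
    dt: float = 0.001
    max_time: float = 30.0

    def validate(self) -> "CohortConfig":
        if self.task not in ("TD", "PD"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_patients < 0 or self.n_controls < 0 or \
                self.n_patients + self.n_controls == 0:
            raise ValueError("group sizes must be non-negative and not both zero")
        for g in GROUPS:
            self.hyper[g].validate()
        return self


@dataclass
class CohortBundle:
    """A generated study: design, per-subject data and the ground truth."""

    config: CohortConfig
    design: pd.DataFrame
    data: pd.DataFrame          # subject_id, group, trial_index, boundary, rt, ...
    truth: pd.DataFrame         # one row per subject: generating parameters
    seed: int

    def merged(self) -> pd.DataFrame:
        """Long table: one row per trial with design columns attached."""
        return self.data.merge(self.design, on="trial_index", how="left")

    def save(self, path) -> None:
        path = Path(path)
        (path / "designs").mkdir(parents=True, exist_ok=True)
        (path / "data").mkdir(exist_ok=True)
        self.design.to_csv(path / "designs" / "design.csv", index=False)
        for sid, g in self.data.groupby("subject_id"):
            g.to_csv(path / "data" / f"{sid}.csv", index=False)
        truth = {
            "seed": self.seed,
            "hyper": {g: {"means": self.config.hyper[g].means,
                          "precisions": self.config.hyper[g].precisions}
                      for g in GROUPS},
            "subject_columns": list(self.truth.columns),
            "subjects": self.truth.to_dict(orient="list"),
        }
        (path / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        cfg = {"task": self.config.task, "variant": self.config.variant,
               "n_patients": self.config.n_patients,
               "n_controls": self.config.n_controls,
               "design_size": self.config.design_size,
               "dt": self.config.dt, "max_time": self.config.max_time,
               "seed": self.seed}
        (path / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    @classmethod
    def load(cls, path) -> "CohortBundle":
        path = Path(path)
        cfg_d = yaml.safe_load((path / "config.yaml").read_text())
        truth_d = json.loads((path / "truth.json").read_text())
        hyper = {g: GroupHyper(truth_d["hyper"][g]["means"],
                               truth_d["hyper"][g]["precisions"]) for g in GROUPS}
        config = CohortConfig(task=cfg_d["task"], variant=cfg_d["variant"],
                              n_patients=cfg_d["n_patients"],
                              n_controls=cfg_d["n_controls"],
                              design_size=cfg_d["design_size"], hyper=hyper,
                              dt=cfg_d["dt"], max_time=cfg_d["max_time"])
        design = pd.read_csv(path / "designs" / "design.csv")
        data = pd.concat([pd.read_csv(f) for f in sorted((path / "data").glob("*.csv"))],
                         ignore_index=True)
        truth = pd.DataFrame(truth_d["subjects"])[truth_d["subject_columns"]]
        return cls(config, design, data, truth, seed=cfg_d["seed"])


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortBundle:
    """Fully reproducible two-group study bundle with stored ground truth."""
    config = (config or CohortConfig()).validate()
    design = make_design(config.task, config.design_size)
    rng = np.random.default_rng(seed)

    frames, truths = [], []
    sizes = {"patients": config.n_patients, "controls": config.n_controls}
    prefix = {"patients": "P", "controls": "C"}
    for g in GROUPS:
        n = sizes[g]
        if n == 0:
            continue
        subj = sample_subject_params(config.hyper[g], n, seed=int(rng.integers(2**31)))
        subj.insert(0, "subject_id", [f"{prefix[g]}{i + 1:02d}" for i in range(n)])
        subj.insert(1, "group", g)
        truths.append(subj)
        for _, row in subj.iterrows():
            ds = generate_dataset(design, row.drop(["subject_id", "group"]),
                                  config.variant, seed=int(rng.integers(2**31)),
                                  dt=config.dt, max_time=config.max_time)
            ds.insert(0, "subject_id", row["subject_id"])
            ds.insert(1, "group", g)
            frames.append(ds)
    data = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    return CohortBundle(config, design, data, truth, seed=seed)
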