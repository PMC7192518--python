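import numpy as np
import pytest

from valueddm.inference import MCMCConfig, build_model, fit_hierarchical
from valueddm.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def pd_cohort():
    """Desk-scale risky-choice study: 9 patients, 19 controls, 56 trials."""
    return generate_cohort(CohortConfig(task="PD", design_size="reduced"), seed=1)


@pytest.fixture(scope="session")
def pd_ddms_fit(pd_cohort):
    """Sigmoid-drift DDM posterior on the desk cohort (short chains)."""
    spec = build_model("PD", "ddms")
    return fit_hierarchical(pd_cohort.merged(), spec,
                            MCMCConfig(chains=2, warmup=600, draws=600), seed=1)


@pytest.fixture(scope="session")
def small_pd_cohort():
    """Tiny cohort (3 patients / 5 controls) for predictive-check tests."""
    return generate_cohort(
        CohortConfig(task="PD", design_size="reduced", n_patients=3, n_controls=5),
        seed=9)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
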