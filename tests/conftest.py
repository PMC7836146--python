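import numpy as np
import pytest

from natalweight import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120-woman synthetic cohort with default study conditions."""
    return generate_cohort(GeneratorConfig(n=120, seed=9001))


@pytest.fixture(scope="session")
def noiseless_cohort_truth():
    """Cohort with no visit noise, no missingness, no outcome residual."""
    cfg = GeneratorConfig(n=80, seed=4242)
    cfg.trajectory.visit_noise_sd = 0.0
    cfg.missing_rate = 0.0
    cfg.outcome.residual_sd = 0.0
    return generate_cohort(cfg, return_truth=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(77)
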