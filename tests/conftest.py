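import numpy as np
import pytest

from copdsim import default_parameters, init_cohort, make_toy_parameters


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def geometric_params():
    return make_toy_parameters("geometric", death_q=0.2)


@pytest.fixture(scope="session")
def all_smoker_cohort(default_params):
    """100k-patient all-stage cohort of smokers (shared across heavy tests)."""
    return init_cohort(100_000, default_params, stratum="ALL", seed=12345)


def mc_standard_error(outcome, field):
    sd = getattr(outcome, f"sd_{field}")
    return sd / np.sqrt(outcome.n)
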