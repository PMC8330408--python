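import logging

import numpy as np
import pytest

from swallowkit import CohortConfig, EffectConfig, simulate_study

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_cohort_config():
    return CohortConfig(n=8, n_male=4)


@pytest.fixture(scope="session")
def small_study(small_cohort_config):
    """A small dual-rated synthetic study shared across tests."""
    return simulate_study(small_cohort_config, EffectConfig(), seed=3, raters=True)


@pytest.fixture(scope="session")
def default_study():
    """One full-size synthetic study (n=76, 3 boluses, two raters)."""
    return simulate_study(CohortConfig(), EffectConfig(), seed=11, raters=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
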