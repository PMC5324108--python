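import dataclasses

import numpy as np
import pytest

import crcrisk as cr


@pytest.fixture(scope="session")
def panel():
    return cr.default_panel()


@pytest.fixture(scope="session")
def small_config():
    """Default calibration scaled down to a 300-case study."""
    return dataclasses.replace(cr.GeneratorConfig.default(),
                               n_cases=300, n_controls=600)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A 300/600 synthetic cohort with propensity score attached."""
    cohort = cr.generate_cohort(small_config, seed=11)
    return cr.attach_propensity(cohort, cr.fit_propensity(cohort))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size (1336/2744) default-calibration cohort with ps."""
    cohort = cr.generate_cohort(cr.GeneratorConfig.default(), seed=43)
    return cr.attach_propensity(cohort, cr.fit_propensity(cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
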