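import numpy as np
import pytest

from keravec import PopulationParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest paired cohort under the default study conditions."""
    return generate_cohort(PopulationParams(n=300, seed=7))


@pytest.fixture(scope="session")
def full_cohort():
    """Full-size paired cohort (854 eyes) under the default conditions."""
    return generate_cohort(PopulationParams(n=854, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
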