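import numpy as np
import pytest

from cogpoint import default_scenarios, generate_cohort


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def cohort192(scenarios):
    """One default four-biomarker cohort at the study's group sizes."""
    return generate_cohort(scenarios, 95, 97, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
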