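import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thbr1 import default_params, generate_curves, study_fields
from thbr1.params import PUBLISHED_R1I

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fields3():
    """The three study-field contexts keyed by nominal tesla."""
    return study_fields()


@pytest.fixture(scope="session")
def table1_params():
    """Published shared parameters with the calibrated default coupling."""
    return default_params()


@pytest.fixture(scope="session")
def published_r1i():
    return dict(PUBLISHED_R1I)


@pytest.fixture(scope="session")
def noiseless_curves(table1_params, published_r1i):
    """Three-field forward-model curves without noise."""
    return generate_curves(table1_params, published_r1i, noise_sd=0.0,
                           seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
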