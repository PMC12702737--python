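import numpy as np
import pytest
from hypothesis import settings

from neuroaffect import default_generative_config, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_config():
    return default_generative_config()


@pytest.fixture(scope="session")
def ref_cohort_frame(ref_config):
    """Default reference cohort (n = 50, seed 42)."""
    return generate_cohort(ref_config).to_frame()


@pytest.fixture(scope="session")
def big_cohort_frame(ref_config):
    """Large cohort for parameter-recovery and moment checks (n = 100,000)."""
    return generate_cohort(ref_config.with_(n_participants=100_000)).to_frame()


@pytest.fixture(scope="session")
def noiseless_config(ref_config):
    return ref_config.with_(noise_sd_positive=0.0, noise_sd_negative=0.0,
                            n_participants=100)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
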