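import numpy as np
import pytest

from cinestrain.synthetic import (
    AcquisitionParams,
    GroupSpec,
    default_distributions,
    sample_subject,
    synthesize_cine,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def healthy_group():
    return GroupSpec(sex="female", age_band="55-64", health="healthy")


@pytest.fixture(scope="session")
def noise_free_acq():
    return AcquisitionParams(n_slices=8, jitter_sd_mm=0.0)


@pytest.fixture(scope="session")
def subject(healthy_group):
    return sample_subject(healthy_group, rng_seed=42)


@pytest.fixture(scope="session")
def clean_stack(subject, noise_free_acq):
    """Jitter-free 8-slice cine stack for one subject."""
    return synthesize_cine(subject, noise_free_acq, rng_seed=7)


@pytest.fixture(scope="session")
def distributions():
    return default_distributions()
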