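import warnings

import numpy as np
import pytest

import fekf


@pytest.fixture(scope="session")
def mixture30():
    """One 30 s simulated abdominal record shared across pipeline tests."""
    return fekf.make_mixture(fekf.MixtureSpec(duration=30.0, seed=42))


@pytest.fixture(scope="session")
def enkf_result(mixture30):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fekf.extract(mixture30.aecg, method="enkf", seed=1)


@pytest.fixture(scope="session")
def ekf_result(mixture30):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fekf.extract(mixture30.aecg, method="ekf", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
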