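import numpy as np
import pytest

from breadthdepth import NoiseModel, PriorSpec


@pytest.fixture(scope="session")
def noise():
    return NoiseModel(1.0)


@pytest.fixture(scope="session")
def gaussian_prior():
    return PriorSpec.gaussian(0.5, 1.0)


@pytest.fixture(scope="session")
def uniform_prior():
    return PriorSpec.uniform_on(0.0, 1.0)


@pytest.fixture(scope="session")
def bimodal_prior():
    return PriorSpec.bimodal(0.5, np.sqrt(1.0 / 12.0))


@pytest.fixture(scope="session")
def all_priors(gaussian_prior, uniform_prior, bimodal_prior):
    return {"gaussian": gaussian_prior, "uniform": uniform_prior, "bimodal": bimodal_prior}
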