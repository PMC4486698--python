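import numpy as np
import pytest

from survtg.data import SurvivalDataset
from survtg.simulation import Scenario, gen_exponential_ph


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """Ten subjects, one covariate, mixed censoring."""
    return SurvivalDataset(
        times=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
        events=[1, 0, 1, 1, 0, 1, 1, 0, 1, 1],
        covariates=np.linspace(-1.5, 1.5, 10)[:, None],
        covariate_names=["z"],
    )


@pytest.fixture(scope="session")
def hr2_dataset():
    """One n=500 uncensored draw from the exponential PH model, HR = 2."""
    sc = Scenario(name="hr2", beta=np.log(2), seed=0)
    return gen_exponential_ph(sc, 0)
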