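import numpy as np
import pytest

from pdrcea import default_parameters, gompertz_life_table


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return gompertz_life_table()


@pytest.fixture(scope="session")
def zero_mortality_table():
    return gompertz_life_table(a=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20200)
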