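import numpy as np
import pytest

from ingarch_monitor import INGARCHParams, negbin, poisson, simulate_path


@pytest.fixture(scope="session")
def pois():
    return poisson()


@pytest.fixture(scope="session")
def nb2():
    return negbin(2)


@pytest.fixture(scope="session")
def h0_series(pois):
    """A moderately long stationary Poisson INGARCH path, shared across tests."""
    rng = np.random.default_rng(20201116)
    return simulate_path(INGARCHParams(2.0, 0.3, 0.3), 2000, pois, rng)
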