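import numpy as np
import pytest

from magnospike import RenewalModelParams, SpikeTrain, simulate_postspike_renewal


@pytest.fixture(scope="session")
def poisson_train() -> SpikeTrain:
    """Long homogeneous Poisson train (rate 5 spikes/s, 10,000 s)."""
    p = RenewalModelParams(input_rate=5.0, seed=1)
    return simulate_postspike_renewal(p, 10_000.0)


@pytest.fixture(scope="session")
def poisson_isis(poisson_train) -> np.ndarray:
    return np.diff(poisson_train.times) * 1000.0


@pytest.fixture()
def regular_train() -> SpikeTrain:
    """101 spikes at 0.25-s spacing."""
    return SpikeTrain(np.arange(101) * 0.25, duration=25.5)
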