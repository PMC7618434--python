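import numpy as np
import pytest

from cendip.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """One default simulated sample shared across tests (seeded)."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def newcdr_bundle():
    """Sample with a seeded new CDR 800 kb from the primary."""
    return simulate(SimConfig(seed=12, new_cdr=(800_000, 0.05)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
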