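import numpy as np
import pytest

from lncpipe import SimConfig, simulate_universe


@pytest.fixture(scope="session")
def universe():
    """Default synthetic study universe (fixed seed)."""
    return simulate_universe(SimConfig(seed=0))


@pytest.fixture(scope="session")
def assembly_by_id(universe):
    return {t.transcript_id: t for t in universe.assembly}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
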