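import numpy as np
import pytest

import intervalbias as ib


@pytest.fixture(scope="session")
def weights():
    return ib.default_weights()


@pytest.fixture(scope="session")
def mt_observer(weights):
    return ib.ObserverParams(ib.ModelTag.MEMORY_TRACE, weights=weights, sigma=0.04)


@pytest.fixture(scope="session")
def naive_observer():
    return ib.ObserverParams(ib.ModelTag.NAIVE, sigma=0.04)


@pytest.fixture(scope="session")
def reference_lower_blocks(mt_observer):
    """Contraction observer in the reference-lower design (49 x 2 blocks)."""
    spec = ib.ProtocolSpec(ib.Protocol.REFERENCE_LOWER)
    cfg = ib.SimulationConfig(
        spec, mt_observer, n_participants=49, blocks_per_participant=2,
        master_seed=101,
    )
    return ib.simulate_experiment(cfg)[0]


@pytest.fixture(scope="session")
def reference_blocks(mt_observer):
    """Contraction observer in the reference design (60 participants)."""
    spec = ib.ProtocolSpec(ib.Protocol.REFERENCE)
    cfg = ib.SimulationConfig(spec, mt_observer, n_participants=60, master_seed=102)
    return ib.simulate_experiment(cfg)[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
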