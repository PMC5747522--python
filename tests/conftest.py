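import pytest

from replaylab.stimulus import LDProtocol
from replaylab.synthetic_cells import CellSpec, ReplaySchedule, make_cell


@pytest.fixture(scope="session")
def protocol_60():
    return LDProtocol(60.0, 60.0, 10)


@pytest.fixture(scope="session")
def noiseless_replay_record():
    """Deterministic (expected-rate) replay cell, 30/30 x 25 cycles."""
    spec = CellSpec(is_replay=True,
                    replay=ReplaySchedule(rel_jitter=0.0),
                    seed=11, cell_id="noiseless")
    return make_cell(spec, LDProtocol(30.0, 30.0, 25), noiseless=True)


@pytest.fixture(scope="session")
def noisy_replay_record():
    """Poisson-sampled replay cell, 60/60 x 10 cycles."""
    spec = CellSpec(is_replay=True, seed=42, cell_id="noisy")
    return make_cell(spec, LDProtocol(60.0, 60.0, 10))
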