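import numpy as np
import pytest

from warmpond import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_config():
    """A fast miniature pond: ~100 agents, high contact rate, 30 cycles."""
    return SimulationConfig(
        experiment="combined",
        max_cycles=30,
        v1_init=60,
        v2_init=40,
        influx_dry=(20, 30),
        influx_wet=(40, 50),
        contact_base=1e-3,
    )
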