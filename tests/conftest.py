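import numpy as np
import pytest

from parfret import InstrumentSpec


@pytest.fixture
def instrument() -> InstrumentSpec:
    """Default instrument: 20 MHz PIE, 25 ns delay, standard distortions."""
    return InstrumentSpec()


@pytest.fixture
def clean_instrument() -> InstrumentSpec:
    """Distortion-free instrument: no background, no crosstalk, gamma 1."""
    return InstrumentSpec(
        bg_rate_donor=0.0,
        bg_rate_acceptor=0.0,
        leakage_alpha=0.0,
        direct_excitation_delta=0.0,
        gamma=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
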