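import numpy as np
import pytest

from ibsense import synth


@pytest.fixture(scope="session")
def small_table():
    """Trial table with a strong planted synchronous preference (12 infants)."""
    return synth.simulate_looking_time_table(
        12, 2500.0, 1000.0, 800.0, 6, seed=202, base_lt_ms=6000.0
    )


@pytest.fixture(scope="session")
def null_table():
    """Trial table with no condition effect."""
    return synth.simulate_looking_time_table(
        12, 0.0, 2000.0, 1500.0, 6, seed=303, base_lt_ms=6000.0
    )


@pytest.fixture(scope="session")
def long_rpeak_train():
    """R-peak train long enough to drive a full 80-trial cardiac session."""
    horizon_ms = 80 * 22.0 * 1000.0
    return synth.simulate_rpeak_train(450.0, 25.0, horizon_ms, seed=77)


@pytest.fixture(scope="session")
def long_resp_trace():
    """Respiration trace long enough to drive a full 80-trial respiratory session."""
    horizon_ms = 80 * 32.0 * 1000.0
    return synth.simulate_respiration(0.7, 1.0, 0.05, horizon_ms, 50.0, seed=78)
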