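import numpy as np
import pytest

from mpbselect import GridSpec, SimulationConfig, default_config, simulate_outbreak


@pytest.fixture(scope="session")
def small_outbreak():
    """A quick 20x20, 13-year synthetic outbreak (states + census)."""
    cfg = default_config(7)
    cfg.grid = GridSpec(20, 20)
    return cfg, *simulate_outbreak(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
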