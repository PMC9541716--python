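import numpy as np
import pytest

from pacemap import SimulationConfig, default_layout, simulate_beats


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def layout_positions(layout):
    return layout[["x_cm", "y_cm"]].to_numpy()


@pytest.fixture(scope="session")
def two_focus_truth():
    """Long two-focus simulation with takeovers, shared across tests."""
    cfg = SimulationConfig(n_foci=2, duration=720.0, seed=0)
    return simulate_beats(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
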