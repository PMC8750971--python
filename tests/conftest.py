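import numpy as np
import pandas as pd
import pytest

from cniscore import (
    SimulationConfig,
    build_panel_from_counts,
    simulate_genome,
    simulate_panel,
)


@pytest.fixture(scope="session")
def small_config():
    """Reduced genome (120 condensed windows) for fast pipeline tests."""
    return SimulationConfig(n_small_windows=1200, n_panel=40, seed=11)


@pytest.fixture(scope="session")
def small_windows(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_panel_counts(small_config, small_windows):
    return simulate_panel(small_windows, small_config)


@pytest.fixture(scope="session")
def small_panel(small_config, small_windows, small_panel_counts):
    return build_panel_from_counts(small_panel_counts, small_windows)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
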