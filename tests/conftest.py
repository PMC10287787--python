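import numpy as np
import pytest

from vorscape import SimulationConfig, gen_categorical_landscape


@pytest.fixture
def lattice_coords():
    """Cell-centre coordinates of a 20x20 unit lattice (n=400)."""
    idx = np.arange(400)
    return np.column_stack([idx % 20 + 0.5, idx // 20 + 0.5]).astype(float)


@pytest.fixture
def patchy_landscape():
    """Mid-sized autocorrelated 6-class landscape used across tests."""
    cfg = SimulationConfig(nrows=60, ncols=60, spatial_range=4.0, seed=11)
    return gen_categorical_landscape(cfg)
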