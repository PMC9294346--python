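import numpy as np
import pytest

from osteoquant import SynthConfig, generate_well


@pytest.fixture(scope="session")
def small_well():
    """A small bright synthetic well (100 cells) shared across tests."""
    return generate_well(
        SynthConfig(width_px=1040, height_px=832, n_cells=100,
                    cell_width_mean_px=20.0, seed=42)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
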