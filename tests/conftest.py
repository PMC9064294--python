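import numpy as np
import pytest

from edequant.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, quick-to-render field with one cell and no noise."""
    return SimulationConfig(image_shape=(96, 96), n_cells=1,
                            cell_radius_um=(2.0, 2.0), shot_noise=False,
                            read_noise_sd=0.0, rng_seed=7)
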