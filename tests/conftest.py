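import numpy as np
import pytest

from mrcquant.simulate import SimulationConfig, generate_cell_image


@pytest.fixture(scope="session")
def two_spot_cell():
    """One noise-free nucleus with two bright bait spots and prey partners."""
    cfg = SimulationConfig(
        n_cells=1,
        image_shape=(128, 128),
        spots_per_cell=2,
        bait_peak=300.0,
        bg_mean=50.0,
        bg_sd=0.0,
        noise_model="none",
        coloc_fraction=1.0,
        seed=42,
    )
    stack, mask, truth = generate_cell_image(cfg)
    return cfg, stack, mask, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
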