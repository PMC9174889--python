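import numpy as np
import pytest

from speckleflow.phantom import AcquisitionConfig, make_flow_map, simulate_speckle_stack


@pytest.fixture(scope="session")
def uniform_stack():
    """One shared 16x16 speckle stack over a uniform flow map (x = 40)."""
    fmap = make_flow_map(16, 16, 0.02, parenchyma_speed=1.0, calibration_a=0.5)
    return simulate_speckle_stack(fmap, AcquisitionConfig(pixel_size=0.02, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
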