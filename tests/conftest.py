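import numpy as np
import pytest

from stromaprog.segmentation import UNetSpec
from stromaprog.synthetic import SceneParams, generate_tile_scene


@pytest.fixture(scope="session")
def small_spec():
    """A fast U-Net geometry (92 -> 52 px) for unit tests."""
    return UNetSpec(depth=2, base_channels=2, input_px=92)


@pytest.fixture(scope="session")
def scene_396():
    """One default 396-px scene with its exact mask."""
    return generate_tile_scene(SceneParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
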