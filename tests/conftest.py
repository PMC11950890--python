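import numpy as np
import pytest

from fillstates import core, synth
from fillstates.volume import MaskVolume, VolumeGrid


@pytest.fixture(scope="session")
def small_config():
    """16^3 phantom for fast unit tests."""
    return synth.PhantomConfig(
        shape=(16, 16, 16),
        roi_semi_axes=(7.0, 6.5, 6.0),
        gm_semi_axes=(7.5, 7.0, 6.5),
        reference_slab_thickness=2,
        field_smoothness=2.0,
        seed=99,
    )


@pytest.fixture(scope="session")
def default_config():
    return synth.PhantomConfig(seed=7)


@pytest.fixture(scope="session")
def small_masks(small_config):
    return synth.make_masks(small_config)


@pytest.fixture(scope="session")
def small_control_model(small_config):
    controls = [synth.generate_control(small_config, 5000 + s) for s in range(30)]
    return core.fit_control_model(controls, "tau")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_grid(rng, shape=(8, 8, 8), modality="raw"):
    return VolumeGrid(rng.normal(1.2, 0.2, size=shape), np.eye(4), modality)


def random_mask(rng, shape=(8, 8, 8), p=0.4):
    vals = rng.random(shape) < p
    vals.flat[0] = True  # never empty
    return MaskVolume(vals, np.eye(4), "test mask")
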