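import numpy as np
import pytest

from slivernet.sliver_model import BackboneConfig
from slivernet.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """The small synthetic preset: 16 slices of 64x64."""
    return SyntheticSpec()


@pytest.fixture(scope="session")
def tiny_backbone_cfg():
    """A minimal stride-8 backbone for fast forward/backward tests."""
    return BackboneConfig(
        in_channels=1,
        stem_channels=4,
        stem_kernel=3,
        stem_stride=2,
        stem_pool=False,
        stage_channels=(4, 6),
        blocks_per_stage=1,
        stage_strides=(2, 2),
    )


@pytest.fixture()
def tiny_volume_batch(rng):
    """(N=2, S=4, 32, 32) float volumes in [0, 1]."""
    return rng.uniform(0, 1, size=(2, 4, 32, 32)).astype(np.float32)
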