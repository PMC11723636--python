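import numpy as np
import pytest

from dualrecon.coils import acquire
from dualrecon.synthetic import (CoilGeometry, biot_savart_maps, expand_to_coils,
                                 make_phantom)
from dualrecon.transforms import SamplingMask, vd_mask


@pytest.fixture(scope="session")
def geometry64():
    return CoilGeometry.default(8, 64)


@pytest.fixture(scope="session")
def maps64(geometry64):
    return biot_savart_maps(geometry64, (64, 64))


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom((64, 64), seed=3)


@pytest.fixture(scope="session")
def multicoil64(phantom64, maps64, geometry64):
    return expand_to_coils(phantom64.image, maps64, geometry64, seed=3)


@pytest.fixture
def full_mask64():
    return SamplingMask(lines=np.ones(64, dtype=np.uint8), af_nominal=1.0001,
                        center_fraction=0.5, sigma=0.15, seed=0)


@pytest.fixture
def empty_mask64():
    return SamplingMask(lines=np.zeros(64, dtype=np.uint8), af_nominal=64.0,
                        center_fraction=0.0, sigma=0.15, seed=0)


@pytest.fixture
def acquired_af2(multicoil64):
    mask = vd_mask(64, 2, seed=5)
    return acquire(multicoil64.frame_kspace(0), mask)
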