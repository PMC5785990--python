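import numpy as np
import pytest

from octhaze.synthetic import (
    AcquisitionSetting,
    PhantomGeometry,
    PhantomOptics,
    make_phantom,
)


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def clean_optics():
    return PhantomOptics(base_noise_sd=0.0)


@pytest.fixture(scope="session")
def in_focus():
    return AcquisitionSetting("middle", 100, 0)


@pytest.fixture(scope="session")
def clean_scan(geometry, clean_optics, in_focus):
    """Noise-free, in-focus, middle-positioned phantom."""
    return make_phantom(geometry, clean_optics, in_focus, seed=0)
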