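import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pamarker import (
    AcquisitionParams,
    Absorber,
    ImageGrid,
    OpticalModel,
    Phantom,
    Scatterer,
    make_linear_array,
)


@pytest.fixture
def linear_array():
    """Full-size handheld probe: 128 elements, 0.3 mm pitch, 5 MHz."""
    return make_linear_array()


@pytest.fixture
def small_array():
    """Small linear array for fast unit tests."""
    return make_linear_array(n_elements=16, pitch=0.6e-3)


@pytest.fixture
def acq():
    return AcquisitionParams(sampling_rate=40e6, n_samples=2048)


@pytest.fixture
def acq_short():
    return AcquisitionParams(sampling_rate=40e6, n_samples=1024)


@pytest.fixture
def point_phantom():
    """One ideal point absorber at (0, 20 mm) in a non-attenuating medium."""
    return Phantom(
        absorbers=[Absorber(position=(0.0, 0.0, 20e-3), amplitude=1.0)],
        optics=OpticalModel(mu_eff=0.0),
    )


@pytest.fixture
def point_scatterer_phantom():
    return Phantom(
        scatterers=[Scatterer(position=(0.0, 0.0, 20e-3), reflectivity=1.0)],
        optics=OpticalModel(mu_eff=0.0),
    )


@pytest.fixture
def point_grid():
    """Grid bracketing the 20 mm point target."""
    return ImageGrid(
        x_min=-4e-3, x_max=4e-3, z_min=16e-3, z_max=24e-3, pixel_spacing=0.1e-3
    )
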