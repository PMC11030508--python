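import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles helpers

from organoidqpi.phantoms import AcquisitionSpec, PhantomSpec, generate_organoid_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom spec used across tests (256 µm field, 1 µm/px)."""
    return PhantomSpec(
        image_size=256,
        organoid_axes=(110.0, 95.0),
        rosette_count=4,
        rosette_radius_range=(18.0, 26.0),
        fissure_count=2,
        droplet_area_fraction=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_organoid_phantom(small_spec)


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionSpec(snr_db=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
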