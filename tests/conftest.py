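import numpy as np
import pytest

from bremstomo import default_library, default_camera, point_source_phantom


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def water_table(lib):
    return lib.table("water")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def parallel_camera():
    return default_camera("parallel")


@pytest.fixture(scope="session")
def pinhole_camera():
    return default_camera("pinhole")


@pytest.fixture(scope="session")
def point_phantom_10cm():
    """Point source at 20 cm detector distance under ~10 cm of water,
    with the default 1 cm perpex shell."""
    return point_source_phantom(10.0)
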