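import numpy as np
import pytest

from sageplan.catalog import PreparedLandscape
from sageplan.geodata import RasterGrid
from sageplan.synth import BundleConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale bundle for fast catalog tests."""
    return generate_bundle(11, BundleConfig(shape=(40, 40), n_leks=6))


@pytest.fixture(scope="session")
def small_prep(small_bundle):
    return PreparedLandscape(small_bundle)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study-condition bundle (100x100 cells, 30 m)."""
    return generate_bundle(42)


@pytest.fixture(scope="session")
def default_prep(default_bundle):
    return PreparedLandscape(default_bundle)


@pytest.fixture
def grid33():
    return RasterGrid(np.ones((3, 3)), cell_size=30.0, origin=(0.0, 900.0))
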