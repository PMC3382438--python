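import numpy as np
import pytest

import blobtomo as bt


@pytest.fixture(scope="session")
def params():
    return bt.BlobParams()


@pytest.fixture(scope="session")
def table(params):
    return bt.make_footprint_table(params)


@pytest.fixture(scope="session")
def paired_geom():
    """8 tilt views symmetric about zero (no 0 degree view), 32 detector bins."""
    return bt.make_geometry([-60.0, -45.0, -30.0, -15.0, 15.0, 30.0, 45.0, 60.0], 32)


@pytest.fixture(scope="session")
def grid16():
    return bt.PixelGrid(16, 16)


@pytest.fixture(scope="session")
def grid32():
    return bt.PixelGrid(32, 32)


@pytest.fixture(scope="session")
def dense_w(paired_geom, grid16, params):
    """Dense brute-force weight matrix on the small reference geometry."""
    return bt.dense_oracle(paired_geom, grid16, params)


@pytest.fixture(scope="session")
def ellr16(paired_geom, grid16, params):
    return bt.build(paired_geom, grid16, params, symmetry_level=3)
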