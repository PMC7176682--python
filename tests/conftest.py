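import numpy as np
import pytest

from landflow import (LandscapeConfig, generate_landscape, generate_catalog,
                      Raster)


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(study_height=40, study_width=40, cell_size=10.0,
                           n_categories=3, coverage=0.08, water_fraction=0.06,
                           seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_catalog():
    return generate_catalog(3, seed=7)


@pytest.fixture
def uniform_raster():
    """11x11 unit-resistance raster."""
    return Raster(np.ones((11, 11)), cell_size=1.0)
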