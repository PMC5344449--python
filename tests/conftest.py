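import numpy as np
import pytest

from nirstroop.geometry import (default_analysis_grid, default_probe_layout,
                                interpolation_weights)


@pytest.fixture(scope="session")
def layout():
    return default_probe_layout()


@pytest.fixture(scope="session")
def grid(layout):
    return default_analysis_grid(layout)


@pytest.fixture(scope="session")
def channel_coords(layout):
    return layout.channel_coordinates()


@pytest.fixture(scope="session")
def kernel_weights(channel_coords, grid):
    """Default-FWHM interpolation weights, shared across tests."""
    return interpolation_weights(channel_coords, grid, kernel_fwhm=15.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20170309)
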