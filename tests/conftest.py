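import numpy as np
import pytest

import specfrac as sf


@pytest.fixture(scope="session")
def grid17():
    """The 17-channel 418-584 nm acquisition grid (9.8 nm steps)."""
    return sf.build_channel_grid(418, 584, 9.8)


@pytest.fixture(scope="session")
def grid29():
    """The 29-channel 418-700 nm acquisition grid (9.8 nm steps)."""
    return sf.build_channel_grid(418, 700, 9.8)


@pytest.fixture(scope="session")
def refs2(grid17):
    return sf.two_state_references(grid17)


@pytest.fixture(scope="session")
def refs4(grid29):
    return sf.four_component_references(grid29)


@pytest.fixture(scope="session")
def small_cell_scene(grid17):
    """Noiseless 64 px cell phantom (defaults except size/droplets, for speed)."""
    return sf.make_cell_scene(grid17, shape=(64, 64), n_droplets=4,
                              droplet_radius_px=2.0, seed=11)


@pytest.fixture(scope="session")
def uniform_stack(grid17):
    counts = np.full((grid17.n_channels, 4, 5), 7.0)
    return sf.LambdaStack(counts, grid17)
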