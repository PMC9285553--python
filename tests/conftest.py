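import numpy as np
import pytest

from dtiphantom.io import protocol_scheme
from dtiphantom.phantom import PhantomLayout, TubeSpec, default_layout, simulate_signal


@pytest.fixture(scope="session")
def seven_tube_layout():
    """Default seven-tube layout on a single slice (fast fits)."""
    return default_layout(grid_shape=(48, 48, 1))


@pytest.fixture(scope="session")
def single_tube_layout():
    """One water tube on a small grid, for quick Monte-Carlo checks."""
    return PhantomLayout(
        tubes=(TubeSpec(1, 0.0, (15.0, 15.0), 10.0, 1.113e-3),),
        grid_shape=(12, 12, 1),
        voxel_size=(2.5, 2.5, 8.0),
    )


@pytest.fixture(scope="session")
def noise_free_stack(seven_tube_layout):
    """Single-repetition noise-free stack of the seven-tube phantom."""
    return simulate_signal(seven_tube_layout, protocol_scheme(0.0, 1))
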