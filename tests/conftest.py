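import numpy as np
import pytest

from retrack import (
    BinaryMask,
    Grid,
    PhantomConfig,
    TensorField,
    generate_phantom,
)

# Small phantoms shared across test modules.  Sizes are chosen so the whole
# default suite stays fast; the acceptance tests use the full-size phantom.

SMALL_ARC = PhantomConfig(grid_shape=(32, 32, 32), arc_radius=14.0, tube_radius=5.0)
STRAIGHT = PhantomConfig(
    grid_shape=(40, 24, 24), arc_radius=14.0, tube_radius=5.0, geometry="straight"
)


@pytest.fixture(scope="session")
def small_arc_phantom():
    return generate_phantom(SMALL_ARC)


@pytest.fixture(scope="session")
def straight_phantom():
    return generate_phantom(STRAIGHT)


@pytest.fixture(scope="session")
def noisy_arc_phantom():
    return generate_phantom(
        PhantomConfig(grid_shape=(32, 32, 32), arc_radius=14.0, tube_radius=5.0,
                      noise_level=2, rng_seed=7)
    )


@pytest.fixture
def homogeneous_prolate_field():
    """Constant prolate tensor field aligned with +x (40x20x20 voxels, 2 mm)."""
    coeffs = np.zeros((40, 20, 20, 6))
    coeffs[..., 0] = 1.7e-3
    coeffs[..., 3] = 0.3e-3
    coeffs[..., 5] = 0.3e-3
    return TensorField(coeffs, Grid((40, 20, 20), 2.0, np.ones(3)))


def truth_mask(phantom) -> BinaryMask:
    return BinaryMask(phantom.truth.bundle_mask, phantom.truth.grid)
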