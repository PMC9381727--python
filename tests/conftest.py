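import numpy as np
import pytest
from dataclasses import replace

from vitrevol import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_spec():
    """Two-intensity disjoint phantom (PMP + CC, no canal, no speckle)."""
    return PhantomSpec(
        grid_shape=(96, 72, 40), speckle_shape=None, seed=3
    ).with_default_cavities(None)


@pytest.fixture(scope="session")
def noiseless_eye(noiseless_spec):
    return generate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def connected_spec():
    """Phantom with a 0.3 mm PMP-CC canal, mild speckle, small grid."""
    spec = PhantomSpec(grid_shape=(128, 96, 48), seed=9, speckle_shape=30.0)
    return spec.with_default_cavities(0.3)


@pytest.fixture(scope="session")
def connected_eye(connected_spec):
    return generate_phantom(connected_spec)


@pytest.fixture(scope="session")
def digitized_sphere():
    """Binary sphere r=20 voxels centered on the grid."""
    r, pad = 20, 4
    n = 2 * (r + pad) + 1
    c = (n - 1) / 2
    x, y, z = np.ogrid[:n, :n, :n]
    return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r * r, r
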