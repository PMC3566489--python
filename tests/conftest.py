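import numpy as np
import pytest

from planecast import PhantomSpec, Volume, generate


@pytest.fixture
def unit_cube() -> Volume:
    """2x2x2-vertex volume with unit spacing: the box is [0, 1]^3."""
    return Volume(values=np.zeros((2, 2, 2)), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def affine_spec() -> PhantomSpec:
    """f(x, y, z) = 1 + 2x + 3y + 5z on a 9^3 unit-spacing grid."""
    return PhantomSpec("affine", extents=(9, 9, 9), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def affine_volume(affine_spec) -> Volume:
    return generate(affine_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130122)


def random_interior_points(volume: Volume, rng, n: int) -> np.ndarray:
    """Strictly interior world points, away from the box faces."""
    box = volume.box_max
    return rng.uniform(0.05, 0.95, size=(n, 3)) * box


def random_ray_through(volume: Volume, rng):
    """A ray aimed at a random interior target from a random direction."""
    from planecast import Ray

    target = random_interior_points(volume, rng, 1)[0]
    direction = rng.normal(size=3)
    while np.linalg.norm(direction) < 1e-6:
        direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    origin = target - direction * (float(np.linalg.norm(volume.box_max)) + 1.0)
    return Ray(origin=origin, direction=direction)
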