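import numpy as np
import pytest

from fibertomo import GridGeometry, ParticleSet, PhantomSpec, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return GridGeometry((24, 24, 24), (2.0, 2.0, 2.0))


def random_particles(rng, geometry: GridGeometry, n: int) -> ParticleSet:
    extent = np.asarray(geometry.shape) * np.asarray(geometry.voxel_size)
    coords = rng.uniform(0.0, extent, size=(n, 3)) + np.asarray(geometry.origin)
    return ParticleSet(coords)


@pytest.fixture
def tiny_phantom_spec():
    """A small, quick phantom used by several modules' tests."""
    return PhantomSpec(volume_shape=(40, 64, 64), voxel_size=4.0, n_fibers=2, seed=5)


def straight_fiber_phantom(fiber_radius=75.0, shape=(96, 96, 192), h=4.0, seed=7,
                           **kwargs):
    """Single straight fiber along x through the volume centre."""
    import fibertomo as ft

    ext = np.array(shape) * h
    line = np.array(
        [[ext[0] / 2, ext[1] / 2, 20.0], [ext[0] / 2, ext[1] / 2, ext[2] - 20.0]]
    )
    spec = PhantomSpec(
        volume_shape=shape, voxel_size=h, n_fibers=1, fiber_radius=fiber_radius,
        seed=seed, **kwargs,
    )
    return ft.decorate_and_render(spec, [line]), line
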