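"""Local density maps, radius sweeps, plateau detection, fiber segmentation."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import fibertomo as ft
from fibertomo import (
    DensityParams,
    GridGeometry,
    ParticleSet,
    RadiusSweep,
    density_map,
    detect_plateaus,
    segment_fibers,
    sweep_radii,
)
from fibertomo.errors import EmptyParticleSetError, EmptySegmentationError

from conftest import random_particles


def voxel_centers(geometry: GridGeometry) -> np.ndarray:
    axes = [
        geometry.origin[i] + (np.arange(geometry.shape[i]) + 0.5) * geometry.voxel_size[i]
        for i in range(3)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)


def brute_force_density(particles, geometry, k, radius):
    """O(N*V) all-pairs oracle for the k-capped range count."""
    centers = voxel_centers(geometry)
    d2 = cdist(centers, particles.coords, "sqeuclidean")
    counts = (d2 <= radius * radius).sum(axis=1)
    return np.minimum(counts, k).reshape(geometry.shape)


class TestDensityMap:
    def test_single_particle_indicator_ball(self):
        geom = GridGeometry((20, 20, 20), (4.0, 4.0, 4.0))
        p = ParticleSet(np.array([[40.0, 40.0, 40.0]]))
        dm = density_map(p, geom, DensityParams(40, 50.0))
        d = np.linalg.norm(voxel_centers(geom) - p.coords[0], axis=1)
        expected = (d <= 50.0).astype(np.float32).reshape(geom.shape)
        np.testing.assert_array_equal(dm.data, expected)

    def test_capped_by_k(self):
        geom = GridGeometry((4, 4, 4), (2.0, 2.0, 2.0))
        rng = np.random.default_rng(0)
        p = ParticleSet(rng.uniform(2.0, 6.0, size=(60, 3)))
        dm = density_map(p, geom, DensityParams(40, 50.0))
        assert dm.data.max() == 40

    def test_empty_particles_raise(self, small_grid):
        with pytest.raises(EmptyParticleSetError):
            density_map(ParticleSet(np.empty((0, 3))), small_grid, DensityParams(40, 10.0))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed, small_grid):
        rng = np.random.default_rng(seed)
        p = random_particles(rng, small_grid, 300)
        radius = 3 * small_grid.voxel_size[0]
        dm = density_map(p, small_grid, DensityParams(40, radius))
        np.testing.assert_array_equal(
            dm.data, brute_force_density(p, small_grid, 40, radius)
        )

    def test_anisotropic_voxels(self, rng):
        geom = GridGeometry((10, 14, 18), (6.0, 3.0, 2.0))
        p = random_particles(rng, geom, 80)
        dm = density_map(p, geom, DensityParams(10, 9.0))
        np.testing.assert_array_equal(dm.data, brute_force_density(p, geom, 10, 9.0))

    def test_monotone_support_in_radius(self, rng, small_grid):
        p = random_particles(rng, small_grid, 50)
        prev = None
        for r in (4.0, 8.0, 16.0):
            support = density_map(p, small_grid, DensityParams(40, r)).data >= 1
            if prev is not None:
                assert np.all(support[prev])
            prev = support

    def test_translation_equivariance(self, rng, small_grid):
        p = random_particles(rng, small_grid, 60)
        dm = density_map(p, small_grid, DensityParams(40, 10.0))
        shift = np.array([13.0, -7.0, 5.0])
        moved = GridGeometry(
            small_grid.shape, small_grid.voxel_size, tuple(shift)
        )
        dm2 = density_map(ParticleSet(p.coords + shift), moved, DensityParams(40, 10.0))
        np.testing.assert_array_equal(dm.data, dm2.data)

    def test_gaussian_kernel_variant(self, rng, small_grid):
        p = random_particles(rng, small_grid, 30)
        dm = density_map(p, small_grid, DensityParams(40, 12.0), kernel="gaussian")
        assert dm.data.max() > 0
        # oracle: truncated gaussian sum
        d = cdist(voxel_centers(small_grid), p.coords)
        sigma = 6.0
        w = np.where(d <= 18.0, np.exp(-d * d / (2 * sigma * sigma)), 0.0).sum(axis=1)
        np.testing.assert_allclose(dm.data.ravel(), w, atol=1e-5)

    def test_decimated_approximates_full(self, rng):
        geom = GridGeometry((24, 24, 24), (4.0, 4.0, 4.0))
        p = random_particles(rng, geom, 200)
        full = density_map(p, geom, DensityParams(40, 20.0))
        dec = density_map(p, geom, DensityParams(40, 20.0), decimate=2)
        assert dec.data.shape == full.data.shape
        assert np.mean(np.abs(dec.data - full.data)) < 1.0


class TestSweep:
    def test_single_particle_count_one_everywhere(self):
        geom = GridGeometry((16, 16, 16), (4.0, 4.0, 4.0))
        p = ParticleSet(np.array([[32.0, 32.0, 32.0]]))
        sw = sweep_radii(p, geom, [8.0, 16.0, 24.0], k=40)
        np.testing.assert_array_equal(sw.object_counts, [1, 1, 1])

    def test_single_entry_sweep(self, rng, small_grid):
        p = random_particles(rng, small_grid, 20)
        sw = sweep_radii(p, small_grid, [6.0], k=40)
        assert len(sw.radii) == 1 and len(sw.object_counts) == 1

    def test_two_tight_clusters_descend_to_two(self):
        rng = np.random.default_rng(3)
        geom = GridGeometry((24, 24, 48), (4.0, 4.0, 4.0))
        a = rng.normal([48, 48, 40], 6.0, size=(25, 3))
        b = rng.normal([48, 48, 150], 6.0, size=(25, 3))
        p = ParticleSet(np.concatenate([a, b]))
        radii = np.array([4.0, 12.0, 24.0, 36.0, 48.0])
        sw = sweep_radii(p, geom, radii, k=40, min_object_voxels=1)
        assert sw.object_counts[0] > 2
        assert 2 in sw.object_counts
        two_at = np.flatnonzero(sw.object_counts == 2)
        assert len(two_at) >= 2  # stable before merging scales

    def test_sweep_consistent_with_density_map(self, rng, small_grid):
        # the shared multi-radius scatter pass must equal per-radius maps
        from fibertomo.density import _count_objects

        p = random_particles(rng, small_grid, 120)
        radii = [4.0, 8.0, 12.0, 20.0]
        sw = sweep_radii(p, small_grid, radii, k=40)
        singles = [
            _count_objects(density_map(p, small_grid, DensityParams(40, r)))
            for r in radii
        ]
        np.testing.assert_array_equal(sw.object_counts, singles)

    def test_invalid_radii(self, rng, small_grid):
        p = random_particles(rng, small_grid, 5)
        with pytest.raises(ValueError):
            sweep_radii(p, small_grid, [10.0, 5.0], k=40)


class TestPlateaus:
    def make(self, counts, radii=None):
        counts = np.asarray(counts, dtype=float)
        if radii is None:
            radii = 10.0 * (1 + np.arange(len(counts)))
        return RadiusSweep(radii=np.asarray(radii, float), object_counts=counts,
                           n_neighbors=40)

    def test_strictly_decreasing_has_no_plateau(self):
        sw = self.make([100, 80, 60, 40, 20, 10])
        assert detect_plateaus(sw, rel_tol=0.05, min_span=3) == []

    def test_constant_counts_single_plateau_at_middle(self):
        sw = self.make([7, 7, 7, 7, 7], radii=[10, 20, 30, 40, 50])
        assert detect_plateaus(sw) == [30.0]

    def test_two_plateau_reference_curve(self):
        sw = self.make([100, 60, 40, 40, 40, 25, 12, 12, 12, 3],
                       radii=np.arange(10, 101, 10))
        assert detect_plateaus(sw, rel_tol=0.05, min_span=3) == [40.0, 80.0]

    def test_min_span_enforced(self):
        sw = self.make([5, 5, 1, 1, 9, 9])
        assert detect_plateaus(sw, rel_tol=0.05, min_span=3) == []
        with pytest.raises(ValueError):
            detect_plateaus(self.make([1, 1]), min_span=3)

    def test_plateaus_increasing_and_within_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 20, size=12)
            sw = self.make(counts)
            ps = detect_plateaus(sw, rel_tol=0.2, min_span=2)
            assert all(sw.radii[0] <= p <= sw.radii[-1] for p in ps)
            assert ps == sorted(ps)


class TestSegmentFibers:
    def test_single_particle_mask_is_ball(self):
        geom = GridGeometry((20, 20, 20), (4.0, 4.0, 4.0))
        p = ParticleSet(np.array([[40.0, 40.0, 40.0]]))
        fm = segment_fibers(p, geom, 30.0)
        d = np.linalg.norm(voxel_centers(geom) - p.coords[0], axis=1)
        np.testing.assert_array_equal(fm.mask.ravel(), d <= 30.0)

    def test_noiseless_fiber_dice_against_truth(self):
        from conftest import straight_fiber_phantom

        ph, _ = straight_fiber_phantom(fiber_radius=75.0, shape=(64, 64, 96))
        parts, _, _ = ft.detect_particles(ph.volume)
        geom = GridGeometry.from_volume(ph.volume)
        fm = segment_fibers(parts, geom, 75.0)
        inter = (fm.mask & ph.truth_mask).sum()
        dice = 2 * inter / (fm.mask.sum() + ph.truth_mask.sum())
        assert dice >= 0.7

    def test_unreachable_radius_raises_empty_segmentation(self):
        # particles at voxel corners: nearest voxel centre is > 1 nm away,
        # so a 1 nm expansion radius yields an all-zero density map
        geom = GridGeometry((8, 8, 8), (4.0, 4.0, 4.0))
        p = ParticleSet(np.array([[8.0, 8.0, 8.0], [16.0, 20.0, 12.0]]))
        with pytest.raises(EmptySegmentationError):
            segment_fibers(p, geom, 1.0)
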