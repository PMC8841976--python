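"""Phantom generator: centerline statistics, particle placement, rendering."""

import numpy as np
import pytest

import fibertomo as ft
from fibertomo.errors import InvalidSpecError
from fibertomo.phantom import (
    _distance_to_polylines,
    _slerp_fraction,
    _step_direction,
    render_particles,
)


class TestCenterlines:
    def test_no_fibers_gives_empty_list(self):
        spec = ft.PhantomSpec(n_fibers=0, volume_shape=(10, 10, 10))
        assert ft.generate_centerlines(spec) == []

    def test_full_persistence_is_straight(self):
        spec = ft.PhantomSpec(
            volume_shape=(64, 64, 64), voxel_size=4.0, n_fibers=3,
            persistence=1.0, seed=11,
        )
        for line in ft.generate_centerlines(spec):
            steps = np.diff(line, axis=0)
            steps /= np.linalg.norm(steps, axis=1, keepdims=True)
            cos = np.sum(steps[1:] * steps[:-1], axis=1)
            np.testing.assert_allclose(cos, 1.0, atol=1e-9)

    def test_step_length_spacing(self):
        spec = ft.PhantomSpec(volume_shape=(64, 64, 64), voxel_size=4.0,
                              n_fibers=2, step_length=30.0, seed=3)
        for line in ft.generate_centerlines(spec):
            d = np.linalg.norm(np.diff(line, axis=0), axis=1)
            np.testing.assert_allclose(d, 30.0, rtol=1e-9)

    def test_clipped_to_volume(self):
        spec = ft.PhantomSpec(volume_shape=(30, 40, 50), voxel_size=4.0,
                              n_fibers=4, seed=9)
        ext = spec.extent
        for line in ft.generate_centerlines(spec):
            assert np.all(line >= 0.0) and np.all(line < ext)

    @pytest.mark.parametrize("persistence", [0.0, 0.5, 0.9])
    def test_expected_step_cosine_equals_persistence(self, persistence):
        # Monte-Carlo on the step kernel itself: mean cosine of successive
        # directions within 3 standard errors of the persistence parameter.
        rng = np.random.default_rng(1)
        a = _slerp_fraction(persistence)
        d = np.array([0.0, 0.0, 1.0])
        cos = np.empty(10000)
        for i in range(len(cos)):
            nd = _step_direction(d, rng, a)
            cos[i] = float(nd @ d)
            d = nd
        se = cos.std() / np.sqrt(len(cos))
        assert abs(cos.mean() - persistence) < 3 * max(se, 1e-3)

    def test_invalid_step_length(self):
        with pytest.raises(InvalidSpecError):
            ft.PhantomSpec(step_length=0.0)


class TestDecorateAndRender:
    def test_nothing_to_render(self):
        spec = ft.PhantomSpec(volume_shape=(16, 16, 16), voxel_size=4.0,
                              n_fibers=1, label_density=0.0, noise_density=0.0,
                              seed=2)
        ph = ft.generate_phantom(spec)
        assert len(ph.particles) == 0
        assert not ph.volume.data.any()

    def test_poisson_mean_matches_analytic(self):
        # straight 1000 nm fiber, radius 75 nm, fully interior: the summed
        # particle count over 200 seeds is Poisson with mean 200*lambda*pi*r^2*L
        lam = 2.0e-5
        shape, h = (60, 60, 80), 20.0
        ext = np.array(shape) * h
        line = np.array(
            [[ext[0] / 2, ext[1] / 2, 300.0], [ext[0] / 2, ext[1] / 2, 1300.0]]
        )
        total = 0
        for seed in range(200):
            spec = ft.PhantomSpec(volume_shape=shape, voxel_size=h, n_fibers=1,
                                  fiber_radius=75.0, label_density=lam, seed=seed)
            ph = ft.decorate_and_render(spec, [line])
            total += len(ph.particles)
        mean = 200 * lam * np.pi * 75.0**2 * 1000.0
        assert abs(total - mean) < 3 * np.sqrt(mean)

    def test_all_labeled_particles_within_fiber_radius(self, tiny_phantom_spec):
        ph = ft.generate_phantom(tiny_phantom_spec)
        d = _distance_to_polylines(ph.particles.coords[~ph.is_noise], ph.centerlines)
        assert np.all(d <= tiny_phantom_spec.radius_of(0))

    def test_noiseless_particles_lie_in_truth_mask(self, tiny_phantom_spec):
        ph = ft.generate_phantom(tiny_phantom_spec)
        vs = np.asarray(tiny_phantom_spec.voxel_size)
        idx = np.floor(ph.particles.coords / vs).astype(int)
        idx = np.clip(idx, 0, np.asarray(tiny_phantom_spec.volume_shape) - 1)
        # voxel-centre quantization can leave a particle very near the tube
        # surface in a voxel whose centre is just outside
        assert ph.truth_mask[tuple(idx.T)].mean() > 0.97

    def test_truth_mask_is_exact_distance_criterion(self):
        spec = ft.PhantomSpec(volume_shape=(20, 20, 20), voxel_size=5.0,
                              n_fibers=1, fiber_radius=20.0, seed=4)
        lines = ft.generate_centerlines(spec)
        ph = ft.decorate_and_render(spec, lines)
        centers = np.stack(
            np.meshgrid(*[(np.arange(n) + 0.5) * 5.0 for n in spec.volume_shape],
                        indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        d = _distance_to_polylines(centers, lines).reshape(spec.volume_shape)
        np.testing.assert_array_equal(ph.truth_mask, d <= 20.0)

    def test_noise_particles_outside_tubes(self):
        spec = ft.PhantomSpec(volume_shape=(32, 48, 48), voxel_size=4.0,
                              n_fibers=1, fiber_radius=50.0,
                              noise_density=2e-6, seed=8)
        ph = ft.generate_phantom(spec)
        noise = ph.particles.coords[ph.is_noise]
        assert len(noise) > 0
        d = _distance_to_polylines(noise, ph.centerlines)
        assert np.all(d > 50.0)

    def test_gaussian_blob_mass_additivity(self):
        # interior blobs: rendered integral equals n x (one blob's integral)
        # sigma = radius/2 must be >= the voxel size for the lattice sum of a
        # Gaussian blob to be shift-invariant at the 1e-6 level
        spec = ft.PhantomSpec(volume_shape=(40, 40, 40), voxel_size=4.0,
                              particle_radius=10.0, blob="gaussian",
                              particle_intensity=7.0)
        rng = np.random.default_rng(0)
        coords = rng.uniform(50.0, 110.0, size=(25, 3))
        vol = render_particles(coords, spec)
        single = render_particles(np.array([[80.3, 77.7, 81.1]]), spec)
        total = vol.data.sum(dtype=np.float64)
        one = single.data.sum(dtype=np.float64)
        assert abs(total - 25 * one) < 1e-6 * total

    def test_hard_blob_mass_conservation(self):
        spec = ft.PhantomSpec(volume_shape=(32, 32, 32), voxel_size=4.0,
                              particle_radius=6.0, particle_intensity=3.0)
        rng = np.random.default_rng(1)
        coords = rng.uniform(30.0, 90.0, size=(10, 3))
        vol = render_particles(coords, spec)
        per_particle = [
            render_particles(c[None], spec).data.sum() for c in coords
        ]
        np.testing.assert_allclose(vol.data.sum(), np.sum(per_particle))

    def test_bit_identical_reproducibility(self, tiny_phantom_spec):
        a = ft.generate_phantom(tiny_phantom_spec)
        b = ft.generate_phantom(tiny_phantom_spec)
        assert np.array_equal(a.volume.data, b.volume.data)
        assert np.array_equal(a.particles.coords, b.particles.coords)
        assert np.array_equal(a.truth_mask, b.truth_mask)


class TestSplitEvenOdd:
    def test_two_particles_split_one_each(self):
        spec = ft.PhantomSpec(volume_shape=(16, 16, 16), voxel_size=4.0,
                              label_density=0.0)
        line = np.array([[10.0, 10.0, 10.0], [50.0, 50.0, 50.0]])
        ph = ft.decorate_and_render(spec, [line])
        coords = np.array([[20.0, 20.0, 20.0], [40.0, 40.0, 40.0]])
        ph.particles = ft.ParticleSet(coords)
        a, b = ft.split_even_odd(ph, seed=0)
        na = (a.data > 0).any()
        nb = (b.data > 0).any()
        assert na and nb
        assert a.data.sum() + b.data.sum() == ph.spec.particle_intensity * (
            (a.data > 0).sum() + (b.data > 0).sum()
        )

    def test_sum_of_halves_equals_full(self, tiny_phantom_spec):
        ph = ft.generate_phantom(tiny_phantom_spec)
        a, b = ft.split_even_odd(ph, seed=3)
        np.testing.assert_array_equal(a.data + b.data, ph.volume.data)

    def test_voxel_noise_lowers_high_frequency_fsc(self, tiny_phantom_spec):
        from fibertomo import fsc_curve

        ph = ft.generate_phantom(tiny_phantom_spec)
        a, b = ft.split_even_odd(ph, seed=3)
        an, bn = ft.split_even_odd(ph, seed=3, voxel_noise_sigma=20.0)
        clean = fsc_curve(a, b)
        noisy = fsc_curve(an, bn)
        hi = clean.frequencies > clean.frequencies.max() * 0.6
        assert noisy.fsc[hi].mean() < clean.fsc[hi].mean()


def test_spec_config_roundtrip(tmp_path):
    spec = ft.PhantomSpec(volume_shape=(20, 30, 40), voxel_size=(5.0, 4.0, 4.0),
                          n_fibers=2, fiber_radius=(60.0, 80.0), seed=17)
    ph = ft.generate_phantom(spec)
    from fibertomo.phantom import spec_from_config, write_phantom

    write_phantom(ph, tmp_path, stem="t")
    back = spec_from_config(tmp_path / "t_spec.cfg")
    assert back == spec
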