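import numpy as np
import pytest

from qelast.materials import ElasticMaterial
from qelast.phantom import (
    HARD_MODULUS_PA,
    SOFT_MODULUS_PA,
    PhantomSpec,
    hard_phantom,
    inclusion_phantom,
    make_speckle,
    phantom_displacement_field,
    render_sequence,
    soft_phantom,
)


class TestMakeSpeckle:
    def test_seed_determinism(self):
        a = make_speckle((64, 64), seed=3)
        b = make_speckle((64, 64), seed=3)
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        assert not np.array_equal(make_speckle((64, 64), seed=1),
                                  make_speckle((64, 64), seed=2))

    def test_zero_psf_gives_impulses(self):
        img = make_speckle((64, 64), density=0.01, psf_sigma=0.0, seed=0)
        assert (img == 0).mean() > 0.5  # mostly empty between scatterers

    def test_texture_variance_stabilizes_at_high_density(self):
        # fully developed speckle: normalized variance changes little once
        # scatterers overlap everywhere
        def nvar(d):
            img = make_speckle((128, 128), density=d, psf_sigma=1.2, seed=5)
            return img.var() / img.mean() ** 2

        low_jump = abs(nvar(1.0) - nvar(0.25))
        high_jump = abs(nvar(8.0) - nvar(2.0))
        assert high_jump < low_jump

    def test_normalized_range(self):
        img = make_speckle((64, 64), seed=9)
        assert img.min() >= 0.0 and img.max() == pytest.approx(1.0)


def _uniform_spec(**kw):
    base = dict(body=ElasticMaterial(10e3, 0.495), image_size_px=128, n_frames=4,
                stress_model="uniform", seed=0)
    base.update(kw)
    return PhantomSpec(**base)


class TestPhantomDisplacementField:
    def test_homogeneous_uniform_stress_gives_uniform_strain(self):
        spec = _uniform_spec()
        d = 2.5e-3  # 10% of the 25 mm height
        u, truth = phantom_displacement_field(spec, d)
        eps = -truth["ezz"]
        assert np.allclose(eps, d / spec.image_extent, rtol=1e-9)

    def test_strain_integrates_to_applied_compression(self):
        spec = _uniform_spec()
        d = 3e-3
        _, truth = phantom_displacement_field(spec, d)
        col_integral = np.sum(-truth["ezz"], axis=0) * spec.pixel_size
        assert np.allclose(col_integral, d, atol=1e-10)

    def test_two_layer_series_springs(self):
        """Equal-thickness layers with moduli E and 2E strain 2:1."""
        spec = _uniform_spec()
        d = 2e-3
        E = spec.modulus_map()
        # emulate layers by patching the modulus map through a subclass hook
        class TwoLayer(PhantomSpec):
            def modulus_map(self):
                m = np.full((self.image_size_px, self.image_size_px), 20e3)
                m[self.image_size_px // 2 :] = 10e3
                return m

        spec2 = TwoLayer(**{f.name: getattr(spec, f.name)
                            for f in spec.__dataclass_fields__.values()})
        _, truth = phantom_displacement_field(spec2, d)
        eps = -truth["ezz"]
        top = eps[: 128 // 2 - 2].mean()
        bottom = eps[128 // 2 + 2 :].mean()
        assert bottom / top == pytest.approx(2.0, rel=1e-6)
        col_integral = np.sum(eps, axis=0) * spec2.pixel_size
        assert np.allclose(col_integral, d, atol=1e-10)

    def test_inclusion_column_strain_ratio(self):
        spec = _uniform_spec(
            inclusion=ElasticMaterial(20e3, 0.495),
            inclusion_center=(0.0, 12.5e-3), inclusion_radius=4e-3,
        )
        _, truth = phantom_displacement_field(spec, 2e-3)
        eps = -truth["ezz"]
        centre_col = eps[:, 64]
        # at the inclusion centre (1 mm smoothing does not reach r=4 mm)
        ratio = centre_col[20] / centre_col[64]
        assert ratio == pytest.approx(20e3 / 10e3, rel=0.02)

    def test_lateral_ratio_matches_in_plane_poisson(self):
        spec = _uniform_spec()
        u, truth = phantom_displacement_field(spec, 3e-3)
        # finite-difference exx away from borders
        exx = np.gradient(u.ux, axis=1)
        ezz = np.gradient(u.uz, axis=0)
        nu_prime = -np.median(exx[10:-10, 10:-10] / ezz[10:-10, 10:-10])
        assert nu_prime == pytest.approx(0.495 / 1.495, rel=1e-3)

    def test_transducer_attached_coordinates(self):
        spec = _uniform_spec()
        d = 3e-3
        u, _ = phantom_displacement_field(spec, d)
        assert abs(u.uz[0].mean()) * spec.pixel_size < 1e-6  # surface pinned
        # the bottom row has one integration cell left, hence rel ~ 1/n
        assert u.uz[-1].mean() * spec.pixel_size == pytest.approx(-d, rel=0.01)


class TestRenderSequence:
    def test_zero_compression_constant_sequence(self):
        spec = _uniform_spec(compression_depth=1e-12, n_frames=3, noise_level=0.0)
        ds = render_sequence(spec)
        assert np.allclose(ds.force_log.forces, 0.0, atol=1e-6)
        for f in ds.frames[1:]:
            assert np.allclose(f.image, ds.frames[0].image, atol=1e-6)

    def test_seed_isolation_truth_invariant(self):
        a = render_sequence(_uniform_spec(seed=1))
        b = render_sequence(_uniform_spec(seed=2))
        assert not np.array_equal(a.frames[0].image, b.frames[0].image)
        assert np.array_equal(a.truth["ezz"], b.truth["ezz"])

    def test_rendering_is_reproducible(self):
        a = render_sequence(_uniform_spec(seed=4))
        b = render_sequence(_uniform_spec(seed=4))
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.image, fb.image)

    def test_nonlinear_force_hardening_factor(self):
        lin = _uniform_spec(seed=1)
        nl = _uniform_spec(
            seed=1, body=ElasticMaterial(10e3, 0.495, nonlinearity_gamma=10.0)
        )
        f_lin = render_sequence(lin).force_log
        f_nl = render_sequence(nl).force_log
        eps0 = lin.compression_depth / lin.image_extent
        assert f_nl.forces[-1] / f_lin.forces[-1] == pytest.approx(
            np.exp(3 * 10 * eps0**2), rel=1e-6
        )

    def test_force_consistent_with_effective_stiffness(self):
        spec = _uniform_spec(seed=1)
        ds = render_sequence(spec)
        # uniform stress: sigma0 = E * d / H, F = sigma0 * A1
        sigma0 = 10e3 * spec.compression_depth / spec.image_extent
        A1 = spec.geometry.footprint_area
        assert ds.force_log.forces[-1] == pytest.approx(sigma0 * A1, rel=1e-6)

    def test_dataset_write_layout(self, tmp_path):
        ds = render_sequence(_uniform_spec(seed=2, n_frames=3))
        out = ds.write(tmp_path / "phantom")
        for name in ("cine.tiff", "force.csv", "truth_E.tiff", "meta.json"):
            assert (out / name).exists()


class TestStandardSpecimens:
    def test_reference_moduli(self):
        assert hard_phantom().body.young_modulus == pytest.approx(HARD_MODULUS_PA)
        assert soft_phantom().body.young_modulus == pytest.approx(SOFT_MODULUS_PA)
        inc = inclusion_phantom()
        assert inc.inclusion.young_modulus == pytest.approx(HARD_MODULUS_PA)
        assert inc.body.young_modulus == pytest.approx(SOFT_MODULUS_PA)
        assert inc.inclusion_radius == pytest.approx(4e-3)

    def test_fast_preset_shrinks_grid_and_frames(self):
        spec = hard_phantom().fast()
        assert spec.image_size_px == 256
        assert 2 <= len(spec.frame_times) < 50
        assert spec.frame_times[-1] == pytest.approx(3.0)

    def test_default_conditions(self):
        spec = hard_phantom()
        assert spec.compression_depth == pytest.approx(3e-3)
        assert spec.compression_speed == pytest.approx(1e-3)
        assert spec.frame_rate == pytest.approx(43.0)
        assert spec.image_extent == pytest.approx(25e-3)
        assert len(spec.frame_times) == 130  # 3 s at 43 fps

    def test_inclusion_must_fit_inside_image(self):
        with pytest.raises(ValueError):
            inclusion_phantom(inclusion_center=(12e-3, 12.5e-3))

    def test_compression_capped_at_15_percent(self):
        with pytest.raises(ValueError):
            hard_phantom(compression_depth=5e-3)
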