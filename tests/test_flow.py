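import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from qelast.flow import (
    DisplacementField,
    available_backends,
    compose_fields,
    estimate_flow,
    frame_correlation,
    preprocess,
    track_sequence,
    warp_image,
)
from qelast.materials import ElasticMaterial, Frame
from qelast.phantom import PhantomSpec, render_sequence


def _frame(img, idx=0):
    return Frame(image=np.asarray(img, float), pixel_size=1e-4, time=idx / 43.0,
                 index=idx)


class TestFrameCorrelation:
    def test_identical_images(self, speckle_128):
        assert frame_correlation(speckle_128, speckle_128) == pytest.approx(1.0)

    def test_negated_image(self, speckle_128):
        assert frame_correlation(speckle_128, -speckle_128 + 3.0) == pytest.approx(-1.0)

    def test_noise_level_matches_analytic_value(self, speckle_128):
        # corr(A, A + n) with sigma_n = 0.1 sigma_A is 1/sqrt(1.01)
        rng = np.random.default_rng(5)
        a = speckle_128
        b = a + rng.normal(0, 0.1 * a.std(), a.shape)
        assert frame_correlation(a, b) == pytest.approx(1 / np.sqrt(1.01), abs=0.003)

    def test_affine_intensity_invariance(self, speckle_128):
        rng = np.random.default_rng(6)
        b = speckle_128 + rng.normal(0, 0.05, speckle_128.shape)
        r0 = frame_correlation(speckle_128, b)
        r1 = frame_correlation(3.0 * speckle_128 + 7.0, 0.5 * b - 2.0)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            frame_correlation(np.ones((8, 8)), np.random.default_rng(0).normal(size=(8, 8)))


class TestPreprocess:
    def test_sigma_zero_is_identity(self, speckle_128):
        f = _frame(speckle_128)
        assert np.array_equal(preprocess(f, 0.0).image, f.image)

    def test_impulse_response_is_gaussian(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = preprocess(_frame(img), 2.0).image
        assert np.allclose(out, gaussian_filter(img, 2.0))

    def test_smoothing_reduces_variance(self, speckle_128):
        out = preprocess(_frame(speckle_128), 1.0).image
        assert out.var() < speckle_128.var()


class TestEstimateFlow:
    def test_identical_frames_give_zero_field(self, speckle_128):
        f = _frame(speckle_128)
        u = estimate_flow(f, _frame(speckle_128, 1))
        assert np.max(np.abs(u.uz)) < 0.05
        assert np.max(np.abs(u.ux)) < 0.05

    def test_recovers_rigid_axial_shift(self, speckle_128):
        rows, cols = np.mgrid[0:128, 0:128].astype(float)
        shifted = map_coordinates(speckle_128, [rows - 3.0, cols], order=1,
                                  mode="nearest")
        u = estimate_flow(_frame(speckle_128), _frame(shifted, 1))
        interior = u.uz[10:-10, 10:-10]
        assert np.median(interior) == pytest.approx(3.0, abs=0.2)

    def test_analytic_compression_warp(self, small_dataset):
        ds = small_dataset
        truth = ds.truth["unit_displacement"]
        s = ds.truth["scales"][-1]
        ref = preprocess(ds.frames[0], 1.0)
        tgt = preprocess(ds.frames[-1], 1.0)
        u = estimate_flow(ref, tgt)
        err = np.hypot(u.ux - truth.ux * s, u.uz - truth.uz * s)
        assert np.median(err[10:-16, 10:-10]) < 0.3

    def test_unavailable_backend_lists_installed(self, speckle_128):
        f = _frame(speckle_128)
        with pytest.raises(ValueError) as exc:
            estimate_flow(f, f, backend="deepflow")
        for name in available_backends():
            assert name in str(exc.value)


class TestWarpImage:
    def test_zero_field_is_identity(self, speckle_128):
        u = DisplacementField(np.zeros((128, 128)), np.zeros((128, 128)), 0, 1)
        warped, valid = warp_image(speckle_128, u)
        assert np.allclose(warped, speckle_128)
        assert valid.all()

    def test_integer_shift_is_exact(self, speckle_128):
        u = DisplacementField(np.full((128, 128), 2.0), np.zeros((128, 128)), 0, 1)
        warped, valid = warp_image(speckle_128, u)
        assert np.allclose(warped[:, :-2], speckle_128[:, 2:])
        assert not valid[:, -1].any()

    def test_warp_inverse_roundtrip_psnr(self, speckle_128):
        img = gaussian_filter(speckle_128, 2.0)
        rng = np.random.default_rng(2)
        uz = gaussian_filter(rng.normal(0, 1.5, img.shape), 10)
        ux = gaussian_filter(rng.normal(0, 1.5, img.shape), 10)
        fwd = DisplacementField(ux, uz, 0, 1)
        bwd = DisplacementField(-ux, -uz, 1, 0)
        once, _ = warp_image(img, fwd)
        back, valid = warp_image(once, bwd)
        sel = valid.copy()
        sel[5:-5, 5:-5] &= True
        err = (back - img)[5:-5, 5:-5]
        psnr = 10 * np.log10(img.max() ** 2 / np.mean(err**2))
        assert psnr > 35.0


class TestComposition:
    def test_composition_matches_direct_field(self, small_dataset):
        """A forced mid-sequence reference switch must reproduce the
        direct frame0->last field via warp composition."""
        ds = small_dataset
        pre = [preprocess(f, 1.0) for f in ds.frames]
        mid = len(pre) // 2
        first = estimate_flow(pre[0], pre[mid])
        second = estimate_flow(pre[mid], pre[-1])
        composed = compose_fields(first, second)
        direct = estimate_flow(pre[0], pre[-1])
        sel = np.zeros(composed.shape, bool)
        sel[10:-16, 10:-10] = True
        err = np.hypot(composed.ux - direct.ux, composed.uz - direct.uz)
        assert np.median(err[sel]) < 0.3


class TestTrackSequence:
    def test_static_sequence_no_switches(self, speckle_128):
        frames = [_frame(speckle_128, i) for i in range(4)]
        fields, log = track_sequence(frames)
        assert all(r.rho == pytest.approx(1.0, abs=1e-6) for r in log)
        assert not any(r.switched for r in log)
        for u in fields:
            assert np.max(np.abs(u.uz)) < 0.05

    def test_rho_min_zero_never_switches(self, small_dataset):
        _, log = track_sequence(small_dataset.frames, rho_min=0.0)
        assert not any(r.switched for r in log)

    def test_rho_min_one_switches_every_frame_and_completes(self, small_dataset):
        fields, log = track_sequence(small_dataset.frames, rho_min=1.0)
        assert all(r.switched for r in log)
        assert len(fields) == len(small_dataset.frames) - 1

    def test_pure_noise_replacement_aborts(self, speckle_128):
        rng = np.random.default_rng(11)
        frames = [_frame(speckle_128, 0), _frame(rng.random((128, 128)), 1)]
        with pytest.raises(RuntimeError, match="untrackable"):
            track_sequence(frames)

    def test_cumulative_uz_reaches_compression_at_bottom(self, small_dataset):
        """In transducer-attached coordinates the material near the fixed
        base moves up by the applied compression."""
        ds = small_dataset
        fields, _ = track_sequence(ds.frames)
        d_px = ds.spec.compression_depth / ds.spec.pixel_size
        bottom_band = fields[-1].uz[108:116, 20:108]
        assert np.median(bottom_band) == pytest.approx(-d_px, abs=0.15 * d_px)

    def test_needs_two_frames(self, speckle_128):
        with pytest.raises(ValueError):
            track_sequence([_frame(speckle_128)])
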