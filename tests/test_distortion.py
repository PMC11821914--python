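"""Expansion factor, rigid/non-rigid registration, RMS length-error curves."""

import numpy as np
import pytest
from scipy import ndimage

from memquant import distortion, phantom
from memquant.errors import ParameterError, RegistrationError
from memquant.model import LandmarkSet


class TestExpansionFactor:
    def test_exact_four_fold_scaling(self):
        rng = np.random.default_rng(0)
        pre = rng.uniform(0, 100, (5, 3))
        est = distortion.estimate_expansion_factor(LandmarkSet(pre, 4.0 * pre))
        assert est.factor == pytest.approx(4.0, rel=1e-12)
        assert est.sd == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_ratio_mean(self):
        """Distances {10, 20} -> {42, 76}: ratios {4.2, 3.8}, mean 4.0."""
        est = distortion.expansion_from_distances([10.0, 20.0], [42.0, 76.0])
        assert est.factor == pytest.approx(4.0)
        assert np.allclose(sorted(est.per_pair_ratios), [3.8, 4.2])

    def test_noiseless_recovery_under_rotation(self):
        """Relative error < 1e-2 on noiseless scaled landmark sets."""
        rng = np.random.default_rng(1)
        pre = rng.uniform(0, 50, (6, 3))
        th = 0.4
        rot = np.array([[1, 0, 0],
                        [0, np.cos(th), -np.sin(th)],
                        [0, np.sin(th), np.cos(th)]])
        post = 4.0 * pre @ rot.T + np.array([3.0, -7.0, 11.0])
        est = distortion.estimate_expansion_factor(LandmarkSet(pre, post))
        assert abs(est.factor - 4.0) / 4.0 < 1e-2

    def test_pixel_sizes_enter_physical_distances(self):
        pre = np.array([[0, 0, 0], [0, 0, 10.0]])
        post = np.array([[0, 0, 0], [0, 0, 10.0]])  # same pixels ...
        est = distortion.estimate_expansion_factor(
            LandmarkSet(pre, post), pre_pixel_size_nm=25.0, post_pixel_size_nm=100.0)
        assert est.factor == pytest.approx(4.0)  # ... but 4x coarser pixels

    def test_coincident_landmarks_rejected(self):
        pre = np.array([[0, 0, 0], [0, 0, 0], [0, 1, 1.0]])
        with pytest.raises(ParameterError):
            distortion.estimate_expansion_factor(LandmarkSet(pre, pre + 1))


@pytest.fixture(scope="module")
def big_phantom():
    """256 px field: the 32 px deformation correlation length needs room."""
    return phantom.make_tube_phantom(phantom.PhantomSpec(shape=(8, 256, 256), seed=1))


@pytest.fixture(scope="module")
def textured_plane(default_phantom):
    pre, _, _, _ = phantom.make_distorted_pair(default_phantom, 4.0, 0.0, seed=3)
    return pre.plane()


class TestRigid:
    def test_identity_pair(self, textured_plane):
        tf, aligned = distortion.register_rigid(textured_plane, textured_plane,
                                                angle_range_deg=2, angle_step_deg=0.5)
        assert tf.score > 0.99
        assert abs(tf.angle_deg) < 0.6
        assert np.hypot(*tf.shift_yx) < 0.2

    def test_recovers_three_degree_rotation(self, textured_plane):
        from skimage.transform import rotate
        rotated = rotate(textured_plane, -3.0, preserve_range=True)
        tf, _ = distortion.register_rigid(textured_plane, rotated,
                                          angle_range_deg=5, angle_step_deg=0.25)
        assert tf.angle_deg == pytest.approx(3.0, abs=0.26)

    def test_structureless_noise_fails(self):
        rng = np.random.default_rng(4)
        with pytest.raises(RegistrationError):
            distortion.register_rigid(rng.normal(0, 1, (64, 64)),
                                      rng.normal(0, 1, (64, 64)),
                                      angle_range_deg=1, angle_step_deg=0.5)


class TestNonRigid:
    def test_identical_inputs_give_null_field(self, textured_plane):
        field = distortion.register_nonrigid(textured_plane, textured_plane,
                                             bio_pixel_nm=25.0)
        assert (field.magnitude_nm / 25.0).max() < 0.1

    def test_pure_translation_recovered(self, textured_plane):
        shifted = ndimage.shift(textured_plane, (2.0, 0.0), order=1)
        field = distortion.register_nonrigid(textured_plane, shifted,
                                             bio_pixel_nm=25.0)
        inner = field.mask.copy()
        inner[:8] = inner[-8:] = False
        inner[:, :8] = inner[:, -8:] = False
        assert (field.dy_nm[inner] / 25.0).mean() == pytest.approx(2.0, abs=0.2)
        assert abs((field.dx_nm[inner] / 25.0).mean()) < 0.2

    def test_truth_field_recovery(self, big_phantom):
        """Mean endpoint error under half the 50 nm truth amplitude.

        The pair is constructed pre-aligned, so the non-rigid stage runs on
        the downscaled post directly; a rigid stage would absorb the random
        field's net shift/rotation and make the truth comparison ill-posed.
        """
        errs = []
        for seed in (0, 1, 2):
            pre, post, _, truth = phantom.make_distorted_pair(
                big_phantom, 4.0, 50.0, seed=seed)
            aligned = distortion.downscale_post(post.plane(), 4.0, pre.plane().shape)
            field = distortion.register_nonrigid(pre.plane(), aligned,
                                                 bio_pixel_nm=25.0)
            err = np.hypot(field.dy_nm - truth.dy_nm, field.dx_nm - truth.dx_nm)
            errs.append(err[field.mask].mean())
        assert np.mean(errs) < 25.0


def constant_field(shape, dy, dx, px=25.0):
    return distortion.DeformationField(dy_nm=np.full(shape, dy),
                                       dx_nm=np.full(shape, dx), bio_pixel_nm=px)


class TestRMSCurve:
    bins = np.array([1000.0, 2000.0, 3000.0])

    def test_zero_field(self):
        curve = distortion.rms_error_curve(constant_field((128, 128), 0, 0),
                                           n_pairs_per_bin=200, bins_nm=self.bins,
                                           seed=0)
        assert np.allclose(curve.rms_um, 0.0, atol=1e-12)

    def test_constant_shift_preserves_distances(self):
        curve = distortion.rms_error_curve(constant_field((128, 128), 40.0, -55.0),
                                           n_pairs_per_bin=200, bins_nm=self.bins,
                                           seed=1)
        assert np.allclose(curve.rms_um, 0.0, atol=1e-9)

    def test_uniform_misscaling_closed_form(self):
        """u(x) = 0.01 x gives rms(L) = 0.01 L exactly."""
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        px = 25.0
        field = distortion.DeformationField(dy_nm=0.01 * yy * px,
                                            dx_nm=0.01 * xx * px, bio_pixel_nm=px)
        curve = distortion.rms_error_curve(field, n_pairs_per_bin=300,
                                           bins_nm=self.bins, seed=2)
        assert np.allclose(curve.rms_um, 0.01 * self.bins / 1000.0, rtol=1e-3)

    def test_rotation_of_coordinate_frame_invariance(self):
        """Rotating the field (grid and vectors together by 90 deg) leaves the
        sampled RMS statistics unchanged up to sampling noise."""
        rng = np.random.default_rng(5)
        u = ndimage.gaussian_filter(rng.standard_normal((2, 128, 128)), (0, 16, 16))
        u *= 2.0 / np.sqrt(np.mean(u[0] ** 2 + u[1] ** 2))
        px = 25.0
        f1 = distortion.DeformationField(dy_nm=u[0] * px, dx_nm=u[1] * px,
                                         bio_pixel_nm=px)
        # rotate +90 deg: grid rotates, (dy, dx) -> (dx, -dy)
        f2 = distortion.DeformationField(dy_nm=np.rot90(u[1]) * px,
                                         dx_nm=-np.rot90(u[0]) * px, bio_pixel_nm=px)
        c1 = distortion.rms_error_curve(f1, n_pairs_per_bin=2000, bins_nm=self.bins,
                                        seed=6)
        c2 = distortion.rms_error_curve(f2, n_pairs_per_bin=2000, bins_nm=self.bins,
                                        seed=6)
        assert np.allclose(c1.rms_um, c2.rms_um, rtol=0.15)

    def test_infeasible_bin_reports_zero_pairs(self):
        field = constant_field((32, 32), 0, 0)
        curve = distortion.rms_error_curve(field, n_pairs_per_bin=50,
                                           bins_nm=np.array([1e6]), seed=3)
        assert curve.n_pairs[0] == 0
        assert np.isnan(curve.rms_um[0])

    def test_pipeline_rms_matches_truth_curve(self, big_phantom):
        """Full pipeline (rigid -> nonrigid -> rms) within +/-30% of the curve
        computed directly from the truth field."""
        pre, post, _, truth = phantom.make_distorted_pair(big_phantom, 4.0, 50.0,
                                                          seed=7)
        _, aligned = distortion.register_rigid(pre.plane(), post.plane(), 4.0,
                                               angle_range_deg=1, angle_step_deg=0.5)
        field = distortion.register_nonrigid(pre.plane(), aligned, bio_pixel_nm=25.0)
        bins = np.array([1000.0, 1600.0, 2400.0])
        got = distortion.rms_error_curve(field, n_pairs_per_bin=1500, bins_nm=bins,
                                         mask=field.mask, seed=8)
        want = distortion.rms_error_curve(truth, n_pairs_per_bin=1500, bins_nm=bins,
                                          mask=field.mask, seed=8)
        sel = got.n_pairs >= 100
        assert sel.any()
        assert np.allclose(got.rms_um[sel], want.rms_um[sel], rtol=0.30)
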