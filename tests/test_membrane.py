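"""Continuity statistic along traced membranes and transverse morphometry."""

import numpy as np
import pytest

from memquant import membrane, phantom
from memquant.errors import UnresolvedWallsError
from memquant.model import MembranePath

from conftest import cilium_spec


def path_along_x(y=16.0, z=6.0, x0=2.0, x1=120.0):
    return MembranePath.from_pixel_points([[z, y, x0], [z, y, x1]], 25.0)


class TestPathSampling:
    def test_constant_image(self):
        vol = np.full((12, 32, 128), 7.0)
        prof = membrane.sample_path_intensity(vol, path_along_x(),
                                              bio_pixel_size_nm=25.0)
        assert np.allclose(prof.intensity, 7.0)
        assert prof.sd == 0.0

    def test_linear_ramp_interpolates_exactly(self):
        vol = np.tile(np.arange(128, dtype=float), (12, 32, 1))
        prof = membrane.sample_path_intensity(vol, path_along_x(),
                                              bio_pixel_size_nm=25.0)
        expect = prof.arclength_nm / 25.0 + 2.0  # x coordinate at each sample
        assert np.allclose(prof.intensity, expect, atol=1e-9)

    def test_sample_count_arithmetic(self):
        """A 1200 nm path stepped at 30 nm yields 41 samples."""
        path = MembranePath.from_pixel_points([[0, 0, 0], [0, 0, 48]], 25.0)
        assert path.length_nm == pytest.approx(1200.0)
        prof = membrane.sample_path_intensity(
            np.zeros((1, 1, 49)), path, membrane.GapParams(sampling_step_nm=30.0),
            bio_pixel_size_nm=25.0)
        assert len(prof.intensity) == 41

    def test_out_of_bounds_vertex_named(self):
        path = MembranePath.from_pixel_points([[0, 5, 5], [0, 5, 500]], 25.0)
        with pytest.raises(ValueError, match="vertex 1"):
            membrane.sample_path_intensity(np.zeros((1, 32, 128)), path,
                                           bio_pixel_size_nm=25.0)


def profile_from(values, step_nm=30.0):
    values = np.asarray(values, float)
    s = np.arange(len(values)) * step_nm
    return membrane.IntensityProfile(arclength_nm=s, intensity=values,
                                     mean=float(values.mean()),
                                     sd=float(values.std()), step_nm=step_nm,
                                     path_length_nm=float(s[-1]))


class TestGapDetection:
    def test_flat_profile_has_no_gaps_and_flags_degenerate_sd(self):
        gaps = membrane.detect_gaps(profile_from(np.full(50, 9.0)))
        assert gaps.n_gaps == 0
        assert gaps.flag == "degenerate-sd"

    def test_hand_built_runs_respect_min_length(self):
        """One 90 nm run and one 30 nm run below threshold: only the 90 nm
        run exceeds the 60 nm resolution and counts as a gap."""
        vals = np.tile([110.0, 90.0], 50)  # mean ~100, sd ~10
        vals[20:23] = 60.0  # 3 samples x 30 nm = 90 nm
        vals[60] = 60.0  # 30 nm
        prof = profile_from(vals, step_nm=30.0)
        thr = prof.mean - 2 * prof.sd
        assert 60.0 < thr < 90.0  # construction sanity
        gaps = membrane.detect_gaps(prof, membrane.GapParams(min_gap_len_nm=60.0))
        assert gaps.n_gaps == 1
        s, e = gaps.gaps[0]
        assert e - s == pytest.approx(90.0)

    def test_large_ksd_or_min_len_disables_detection(self):
        rng = np.random.default_rng(0)
        prof = profile_from(rng.normal(100, 10, 200))
        assert membrane.detect_gaps(
            prof, membrane.GapParams(k_sd=50.0)).n_gaps == 0
        assert membrane.detect_gaps(
            prof, membrane.GapParams(min_gap_len_nm=1e9)).n_gaps == 0

    def test_phantom_gap_overlaps_truth(self):
        """An inserted gap is detected at the right place (Jaccard > 0.5)."""
        vol = phantom.make_tube_phantom(cilium_spec(7))
        gapped = phantom.insert_gaps(vol, 0.02, min_gap_len_nm=150.0, seed=70)
        img = phantom.render_image(gapped, seed=71)
        path = phantom.surface_path(gapped, 0)
        prof = membrane.sample_path_intensity(img, path, channel="membrane")
        gaps = membrane.detect_gaps(prof)
        truth = gapped.gaps_truth[0]
        assert gaps.n_gaps >= 1 and len(truth) >= 1

        def jaccard(a, b):
            lo, hi = max(a[0], b[0]), min(a[1], b[1])
            inter = max(0.0, hi - lo)
            union = (a[1] - a[0]) + (b[1] - b[0]) - inter
            return inter / union

        best = max(jaccard(g, t) for g in gaps.gaps for t in truth)
        assert best > 0.5


class TestContinuity:
    def test_no_gaps_is_hundred_percent(self):
        prof = profile_from(np.full(50, 9.0))
        res = membrane.percent_continuity(prof, membrane.GapSet([]))
        assert res.percent_continuity == 100.0

    def test_arithmetic(self):
        """300 nm of gaps on a 10 um path leaves 97.0% continuity."""
        prof = profile_from(np.zeros(1001), step_nm=10.0)  # 10 um
        gaps = membrane.GapSet([(1000.0, 1200.0), (5000.0, 5100.0)])
        res = membrane.percent_continuity(prof, gaps)
        assert res.percent_continuity == pytest.approx(97.0)

    def test_monotone_in_gaps(self):
        prof = profile_from(np.zeros(1001), step_nm=10.0)
        g1 = membrane.GapSet([(1000.0, 1200.0)])
        g2 = membrane.GapSet([(1000.0, 1200.0), (3000.0, 3100.0)])
        r1 = membrane.percent_continuity(prof, g1)
        r2 = membrane.percent_continuity(prof, g2)
        assert r2.percent_continuity < r1.percent_continuity
        assert 0.0 <= r2.percent_continuity <= 100.0


@pytest.fixture(scope="module")
def tube_image(straight_phantom):
    img = phantom.render_image(straight_phantom, seed=41)
    return img.plane(6)


class TestTransverseProfile:
    def test_twin_peaks_normalized_to_one(self, tube_image):
        prof = membrane.transverse_profile(tube_image, (16, 64), 0.0, 40, 24,
                                           bio_pixel_nm=25.0)
        assert prof.normalized.max() == pytest.approx(1.0)
        assert prof.flag == "ok"

    def test_flipping_the_box_reverses_the_profile(self, tube_image):
        p0 = membrane.transverse_profile(tube_image, (16, 64), 0.0, 40, 24,
                                         bio_pixel_nm=25.0)
        p180 = membrane.transverse_profile(tube_image, (16, 64), 180.0, 40, 24,
                                           bio_pixel_nm=25.0)
        assert np.allclose(p0.normalized, p180.normalized[::-1], atol=1e-9)

    def test_constant_image_flags_degenerate(self):
        prof = membrane.transverse_profile(np.full((64, 64), 5.0), (32, 32),
                                           0.0, 20, 20)
        assert prof.flag == "degenerate"

    def test_zero_size_box_rejected(self):
        from memquant.errors import ParameterError
        with pytest.raises(ParameterError):
            membrane.transverse_profile(np.zeros((32, 32)), (16, 16), 0.0, 0, 10)


class TestDiameter:
    def test_analytic_two_gaussian_profile(self):
        """Peaks at +/-150 nm give a 300 nm diameter within one sample."""
        x = np.arange(-300.0, 301.0, 10.0)
        y = np.exp(-(x - 150) ** 2 / (2 * 40 ** 2)) + \
            np.exp(-(x + 150) ** 2 / (2 * 40 ** 2))
        prof = membrane.TransverseProfile(offset_nm=x, intensity=y,
                                          normalized=y / y.max())
        assert membrane.diameter_from_profile(prof) == pytest.approx(300.0, abs=10.0)

    def test_phantom_tube_diameter_within_15pct(self, straight_phantom):
        img = phantom.render_image(straight_phantom, seed=42)
        prof = membrane.transverse_profile(img.plane(6), (16, 64), 0.0, 40, 24,
                                           bio_pixel_nm=25.0)
        assert membrane.diameter_from_profile(prof) == pytest.approx(300.0, rel=0.15)

    def test_intensity_scaling_invariance(self, straight_phantom):
        img = phantom.render_image(straight_phantom, seed=43)
        d = []
        for c in (1.0, 37.0):
            prof = membrane.transverse_profile(c * img.plane(6), (16, 64), 0.0,
                                               40, 24, bio_pixel_nm=25.0)
            d.append(membrane.diameter_from_profile(prof))
        assert d[0] == pytest.approx(d[1], rel=1e-12)

    def test_flat_profile_is_unresolved(self):
        x = np.arange(-100.0, 101.0, 10.0)
        y = np.exp(-x ** 2 / (2 * 80 ** 2))  # single peak
        prof = membrane.TransverseProfile(offset_nm=x, intensity=y,
                                          normalized=y / y.max())
        with pytest.raises(UnresolvedWallsError):
            membrane.diameter_from_profile(prof)


class TestContinuityRecovery:
    @pytest.mark.parametrize("g", [0.0, 0.05])
    def test_mean_recovery_within_two_points(self, g):
        """Measured continuity tracks 100(1-g) within 2 points (5 phantoms
        here; the full 20-phantom, 4-fraction experiment runs in the
        acceptance suite)."""
        vals = []
        for seed in range(5):
            vol = phantom.make_tube_phantom(cilium_spec(seed))
            if g > 0:
                vol = phantom.insert_gaps(vol, g, seed=seed + 1000)
            img = phantom.render_image(vol, seed=seed + 2000)
            path = phantom.surface_path(vol, 0)
            prof = membrane.sample_path_intensity(img, path, channel="membrane")
            res = membrane.percent_continuity(prof, membrane.detect_gaps(prof))
            vals.append(res.percent_continuity)
        assert np.mean(vals) == pytest.approx(100.0 * (1 - g), abs=2.0)
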