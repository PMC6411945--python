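import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from cytoquant.ridges import (
    RidgeParams,
    detect_ridges,
    line_strength_for_contrast,
    mt_density,
    render_ridges,
    sigma_for_line_width,
    thresholds_from_contrast,
)
from cytoquant.synthdata import gen_filaments

SIGMA3 = sigma_for_line_width(3.0)
LINE_PARAMS = RidgeParams(sigma=SIGMA3, upper_threshold=7.0, lower_threshold=2.0,
                          min_length=6.0)


def truth_points(polylines, step=0.5):
    """Densely resampled ground-truth centre-line points."""
    out = []
    for t in polylines:
        t = np.asarray(t)
        seg = np.cumsum(np.r_[0, np.linalg.norm(np.diff(t, axis=0), axis=1)])
        s = np.linspace(0, seg[-1], max(2, int(seg[-1] / step)))
        out.append(np.c_[np.interp(s, seg, t[:, 0]), np.interp(s, seg, t[:, 1])])
    return np.vstack(out)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        dict(sigma=0.0),
        dict(lower_threshold=2.0, upper_threshold=1.0),
        dict(lower_threshold=0.0),
        dict(min_length=-1.0),
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            RidgeParams(**kwargs)

    def test_plugin_sigma_convention(self):
        # sigma = w / (2 sqrt 3) + 0.5
        assert sigma_for_line_width(3.0) == pytest.approx(3 / (2 * math.sqrt(3)) + 0.5)

    def test_contrast_conversion_is_theoretical_peak_strength(self):
        # for a Gaussian line of sd s_l smoothed at sigma the centre
        # strength is h * s_l / (s_l^2 + sigma^2)^{3/2}
        s = line_strength_for_contrast(100, 3.0, 1.5)
        assert s == pytest.approx(100 * 1.5 / (1.5**2 + 1.5**2) ** 1.5)
        up, lo = thresholds_from_contrast(100, 3.0, 1.5)
        assert 0 < lo < up < s


class TestDetect:
    def test_blank_image_empty(self):
        rs = detect_ridges(np.full((32, 32), 5.0), LINE_PARAMS)
        assert len(rs) == 0

    def test_too_small_or_oversmoothed(self):
        with pytest.raises(ValueError):
            detect_ridges(np.zeros((4, 4)), LINE_PARAMS)
        with pytest.raises(ValueError):
            detect_ridges(np.zeros((16, 16)), RidgeParams(sigma=8.0,
                                                          upper_threshold=1,
                                                          lower_threshold=0.5))

    @pytest.mark.parametrize("theta", [0, 20, 45, 67, 90])
    def test_single_straight_line_recovery(self, theta, straight_line_image):
        img, (cy, cx, th) = straight_line_image(theta, length=100)
        # lower threshold ~22% of the theoretical centre strength ends
        # the trace where the line fades, limiting end-cap overshoot
        params = RidgeParams(sigma=SIGMA3, upper_threshold=9.0,
                             lower_threshold=4.0, min_length=10)
        rs = detect_ridges(img, params)
        assert len(rs) == 1
        # arc length within 5% of the true 100 px (small overshoot into
        # the end caps is expected)
        assert rs.polylines[0].arc_length == pytest.approx(100, rel=0.05)
        pts = rs.all_points()
        # sub-pixel localization on the interior of the segment
        proj = (pts[:, 0] - cy) * math.sin(th) + (pts[:, 1] - cx) * math.cos(th)
        perp = -(pts[:, 0] - cy) * math.cos(th) + (pts[:, 1] - cx) * math.sin(th)
        interior = np.abs(proj) <= 48
        rms = math.sqrt(float((perp[interior] ** 2).mean()))
        assert rms <= 0.2  # noiseless sub-pixel accuracy
        assert float(np.abs(perp[interior]).mean()) <= 0.3

    def test_constant_offset_invariance(self, straight_line_image):
        img, _ = straight_line_image(30)
        params = RidgeParams(sigma=SIGMA3, upper_threshold=9.0, lower_threshold=2.7,
                             min_length=10)
        a = detect_ridges(img, params)
        b = detect_ridges(img + 50.0, params)
        assert len(a) == len(b)
        # invariance holds to the numerical precision of the filter
        # cascade (the offset perturbs derivatives only through rounding)
        np.testing.assert_allclose(a.all_points(), b.all_points(), atol=1e-2)

    def test_rotation_equivariance_90deg(self, straight_line_image):
        img, _ = straight_line_image(25)
        params = RidgeParams(sigma=SIGMA3, upper_threshold=9.0, lower_threshold=2.7,
                             min_length=10)
        a = detect_ridges(img, params)
        b = detect_ridges(np.rot90(img), params)
        H = img.shape[1]
        # map rotated points back: rot90 sends (y, x) -> (H-1-x, y)
        pts_b = b.all_points()
        back = np.c_[pts_b[:, 1], H - 1 - pts_b[:, 0]]
        d, _ = cKDTree(a.all_points()).query(back)
        assert d.max() < 0.1
        assert np.sort(np.concatenate([p.strengths for p in a.polylines])) == pytest.approx(
            np.sort(np.concatenate([p.strengths for p in b.polylines])), abs=1e-6)

    def test_filament_field_recall_precision(self):
        stack, gt = gen_filaments(20, peak_intensity=100, noise_sd=12.5,
                                  shape=(256, 256), seed=7)
        rs = detect_ridges(stack.pixels, LINE_PARAMS)
        pts = rs.all_points()
        tp = truth_points(gt.truth["polylines"])
        d, _ = cKDTree(tp).query(pts)
        dt, _ = cKDTree(pts).query(tp)
        assert (d <= 2).mean() >= 0.9  # precision
        assert (dt <= 2).mean() >= 0.9  # recall

    def test_polyline_invariants(self, straight_line_image):
        img, _ = straight_line_image(40)
        rs = detect_ridges(img, LINE_PARAMS)
        for poly in rs.polylines:
            assert len(poly) >= 2
            steps = np.linalg.norm(np.diff(poly.points, axis=0), axis=1)
            assert steps.max() <= 2.0
            assert (poly.strengths > 0).all()
            assert (poly.points >= -0.5).all()
            assert (poly.points[:, 0] <= img.shape[0] - 0.5).all()


class TestRender:
    def test_empty_set_black_canvas(self):
        from cytoquant.ridges import RidgeSet

        canvas = render_ridges(RidgeSet([], (32, 32)), (32, 32))
        assert canvas.dtype == np.uint8 and canvas.sum() == 0

    def test_horizontal_segment_pixel_count(self):
        from cytoquant.ridges import Polyline, RidgeSet

        pts = np.array([[16.0, c] for c in range(10, 20)])
        poly = Polyline(pts, np.tile([1.0, 0.0], (10, 1)), np.ones(10))
        canvas = render_ridges(RidgeSet([poly], (32, 32)), (32, 32), line_width=1)
        assert (canvas == 255).sum() == 10
        assert canvas.mean() == pytest.approx(255 * 10 / 1024)

    def test_deterministic(self, straight_line_image):
        img, _ = straight_line_image(33)
        rs = detect_ridges(img, LINE_PARAMS)
        a = render_ridges(rs, img.shape)
        b = render_ridges(rs, img.shape)
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_and_width(self, straight_line_image):
        from cytoquant.ridges import RidgeSet

        with pytest.raises(ValueError):
            render_ridges(RidgeSet([], (32, 32)), (16, 16))
        with pytest.raises(ValueError):
            render_ridges(RidgeSet([], (32, 32)), (32, 32), line_width=0)


class TestDensity:
    def test_blank_is_zero(self):
        assert mt_density(np.zeros((64, 64)), LINE_PARAMS,
                          rolling_ball_radius=None) == 0.0

    def test_equals_pixel_counting_oracle(self):
        stack, _ = gen_filaments(10, shape=(128, 128), seed=3)
        density = mt_density(stack.pixels, LINE_PARAMS, rolling_ball_radius=None)
        rs = detect_ridges(stack.pixels, LINE_PARAMS)
        canvas = render_ridges(rs, stack.pixels.shape)
        n_white = int((canvas == 255).sum())
        assert density == 255.0 * n_white / canvas.size

    def test_monotone_in_filament_count(self):
        densities = []
        for n in (5, 10, 20):
            stack, _ = gen_filaments(n, shape=(192, 192), seed=11)
            densities.append(mt_density(stack.pixels, LINE_PARAMS,
                                        rolling_ball_radius=None))
        assert densities[0] < densities[1] < densities[2]
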