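import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import feret_all_pairs
from cytoquant.imgio import ImageStack
from cytoquant.kymo import (
    Kymograph,
    MotilityConfig,
    Rect,
    build_kymographs,
    feret_diameter_angle,
    region_motility,
    streak_ridge_params,
    trace_and_score,
    vertical_deviation,
)
from cytoquant.ridges import RidgeParams
from cytoquant.synthdata import gen_drift_movie


def movie_from(frames):
    return ImageStack(np.asarray(frames, float), axes="tyx", frame_interval=1.0)


class TestBuildKymographs:
    def test_counting(self, rng):
        movie = movie_from(rng.uniform(0, 1, (100, 64, 64)))
        kymos = build_kymographs(movie, Rect(10, 12, 40, 30), stride=10)
        x_k = [k for k in kymos if k.line_axis == "x"]
        y_k = [k for k in kymos if k.line_axis == "y"]
        assert len(x_k) == 4 and len(y_k) == 3  # ceil(40/10), ceil(30/10)
        assert all(k.pixels.shape[0] == 100 for k in kymos)
        assert all(k.pixels.shape[1] == 30 for k in x_k)
        assert all(k.pixels.shape[1] == 40 for k in y_k)

    def test_static_movie_rows_identical(self, rng):
        frame = rng.uniform(0, 1, (32, 32))
        movie = movie_from([frame] * 20)
        for k in build_kymographs(movie, Rect(4, 4, 16, 16), stride=4):
            assert (k.pixels == k.pixels[0]).all()

    def test_translating_movie_argmax_slope(self):
        frames = []
        for t in range(30):
            fr = np.zeros((40, 80))
            fr[:, 10 + t] = 100.0  # bright column moving +1 px/frame
            frames.append(fr)
        kymos = build_kymographs(movie_from(frames), Rect(0, 0, 40, 80), stride=40)
        xk = [k for k in kymos if k.line_axis == "x"][0]
        argmax = xk.pixels.argmax(axis=1)
        slopes = np.diff(argmax)
        assert (slopes == 1).all()

    def test_region_bounds_and_stride(self, rng):
        movie = movie_from(rng.uniform(0, 1, (5, 16, 16)))
        with pytest.raises(ValueError):
            build_kymographs(movie, Rect(10, 10, 10, 10))
        with pytest.raises(ValueError):
            build_kymographs(movie, Rect(0, 0, 8, 8), stride=0)


class TestFeret:
    def test_vertical_chord(self):
        pts = np.array([[t, 7.0] for t in range(20)])
        _, ang = feret_diameter_angle(pts)
        assert vertical_deviation(ang) == pytest.approx(0.0)

    def test_unit_slope_is_45_degrees(self):
        pts = np.array([[t, float(t)] for t in range(20)])
        d, ang = feret_diameter_angle(pts)
        assert ang == pytest.approx(45.0)
        assert vertical_deviation(ang) == pytest.approx(45.0)
        assert d == pytest.approx(19 * math.sqrt(2))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_pairs_oracle(self, seed):
        r = np.random.default_rng(seed)
        pts = r.uniform(0, 50, (int(r.integers(2, 40)), 2))
        d, ang = feret_diameter_angle(pts)
        d0, ang0 = feret_all_pairs(pts)
        assert d == pytest.approx(d0, abs=1e-12)
        assert ang == pytest.approx(ang0, abs=1e-9)

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=2, max_size=25))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_hull_route_equals_all_pairs(self, pts):
        """The convex-hull Feret search agrees with exhaustive pairwise
        search on arbitrary point sets, and the deviation stays in
        [0, 90]."""
        pts = np.asarray(pts, float)
        d, ang = feret_diameter_angle(pts)
        d0, _ = feret_all_pairs(pts)
        assert d == pytest.approx(d0, abs=1e-9)
        assert 0.0 <= vertical_deviation(ang) <= 90.0

    def test_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        d, ang = feret_diameter_angle(pts)
        d0, ang0 = feret_all_pairs(pts)
        assert (d, ang) == (pytest.approx(d0), pytest.approx(ang0))

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            feret_diameter_angle(np.array([[1.0, 1.0]]))


def streak_kymo(slope, n_rows=80, width=120, streak_sigma=2.0, peak=100.0):
    """Synthetic kymograph: one streak advancing `slope` columns/row."""
    yy, xx = np.mgrid[0:n_rows, 0:width]
    center = 20.0 + slope * yy
    return Kymograph(peak * np.exp(-0.5 * ((xx - center) / streak_sigma) ** 2),
                     "x", 0)


class TestTraceAndScore:
    def test_vertical_streak_zero_deviation(self):
        k = streak_kymo(0.0)
        devs = trace_and_score(k, RidgeParams(sigma=2.0, upper_threshold=3.0,
                                              lower_threshold=1.0, min_length=20))
        assert devs and max(devs) <= 1.0

    def test_unit_slope_streak_45(self):
        k = streak_kymo(1.0)
        devs = trace_and_score(k, RidgeParams(sigma=2.0, upper_threshold=3.0,
                                              lower_threshold=1.0, min_length=20))
        assert devs
        assert np.mean(devs) == pytest.approx(45.0, abs=2.0)

    def test_blank_kymograph_empty(self):
        k = Kymograph(np.zeros((40, 60)), "y", 3)
        assert trace_and_score(k, RidgeParams(sigma=2.0, upper_threshold=3.0,
                                              lower_threshold=1.0)) == []

    def test_deviations_in_range(self, rng):
        k = Kymograph(rng.uniform(0, 100, (60, 80)), "x", 0)
        devs = trace_and_score(k, RidgeParams(sigma=2.0, upper_threshold=1.0,
                                              lower_threshold=0.3, min_length=5))
        assert all(0.0 <= d <= 90.0 for d in devs)


class TestRegionMotility:
    def test_static_movie_below_two_degrees(self):
        movie, _ = gen_drift_movie(drift_px_per_frame=(0.0, 0.0),
                                   jitter_amplitude_px=0.0, n_frames=150,
                                   shape=(96, 240), seed=3, n_blobs=60)
        cfg = MotilityConfig(axes="both", stride=8,
                             ridge=streak_ridge_params(50, 0.1))
        res = region_motility(movie, [Rect(16, 10, 64, 220)], cfg)
        assert res[0].n_traces > 0
        assert res[0].mean_deviation <= 2.0

    def test_unit_drift_recovers_45(self):
        movie, _ = gen_drift_movie(drift_px_per_frame=(0.0, 1.0),
                                   jitter_amplitude_px=2.0, n_frames=150,
                                   shape=(96, 240), seed=3, n_blobs=60)
        cfg = MotilityConfig(axes="x", stride=8, ridge=streak_ridge_params(50, 1.0))
        res = region_motility(movie, [Rect(16, 10, 64, 220)], cfg)
        assert res[0].mean_deviation == pytest.approx(45.0, abs=5.0)

    def test_time_reversal_symmetry(self):
        movie, _ = gen_drift_movie(drift_px_per_frame=(0.0, 1.0),
                                   jitter_amplitude_px=2.0, n_frames=150,
                                   shape=(96, 240), seed=4, n_blobs=60)
        rev = ImageStack(movie.pixels[::-1].copy(), axes="tyx",
                         pixel_size=movie.pixel_size,
                         frame_interval=movie.frame_interval)
        cfg = MotilityConfig(axes="x", stride=16, ridge=streak_ridge_params(50, 1.0))
        a = region_motility(movie, [Rect(16, 10, 64, 220)], cfg)[0]
        b = region_motility(rev, [Rect(16, 10, 64, 220)], cfg)[0]
        assert a.mean_deviation == pytest.approx(b.mean_deviation, abs=1.5)

    def test_mean_is_mean_of_traces(self):
        movie, _ = gen_drift_movie(drift_px_per_frame=(0.0, 0.5),
                                   jitter_amplitude_px=1.0, n_frames=150,
                                   shape=(96, 240), seed=5, n_blobs=60)
        cfg = MotilityConfig(axes="x", stride=16, ridge=streak_ridge_params(50, 0.5))
        res = region_motility(movie, [Rect(16, 10, 64, 220)], cfg)[0]
        if res.per_trace_deviations:
            assert res.mean_deviation == pytest.approx(
                float(np.mean(res.per_trace_deviations)))
        assert res.n_traces == len(res.per_trace_deviations)

    def test_bad_axes(self):
        movie, _ = gen_drift_movie(n_frames=110, shape=(64, 64), seed=1)
        with pytest.raises(ValueError):
            region_motility(movie, [Rect(0, 0, 32, 32)], MotilityConfig(axes="z"))
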