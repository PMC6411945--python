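import math

import numpy as np
import pytest
import scipy.ndimage as ndi

from cytoquant.comets import (
    CellLabelMap,
    Particle,
    condition_summary,
    detect_comet_particles,
    per_cell_mean_ar,
    segment_cells,
)
from cytoquant.synthdata import gen_comet_field


def gaussian_spot(shape, cy, cx, sigma_major, sigma_minor, theta, peak=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy = yy - cy
    dx = xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return peak * np.exp(-0.5 * ((u / sigma_major) ** 2 + (v / sigma_minor) ** 2))


def one_cell_map(shape):
    return CellLabelMap(np.ones(shape, dtype=np.int32), 1)


class TestSegmentCells:
    def test_blank_junction_single_region(self):
        cells = segment_cells(np.zeros((64, 64)))
        assert cells.n_cells == 1
        assert (cells.labels == 1).all()

    def test_voronoi_tessellation_recovered(self):
        junction, _, gt = gen_comet_field(n_cells=10, comets_per_cell=0,
                                          shape=(256, 256), seed=1)
        cells = segment_cells(junction.pixels, min_cell_area=64)
        assert cells.n_cells == 10
        # every true seed lies in its own label
        seeds = np.asarray(gt.truth["cell_seeds"])
        labels_at_seeds = [cells.labels[int(round(y)), int(round(x))]
                          for y, x in seeds]
        assert sorted(labels_at_seeds) == list(range(1, 11))

    def test_erased_boundary_merges_cells(self):
        junction, _, gt = gen_comet_field(n_cells=10, comets_per_cell=0,
                                          shape=(256, 256), seed=1,
                                          junction_width_px=2.0)
        # reconstruct a noiseless boundary image and erase one wall:
        # remove boundary pixels between the two closest seeds
        seeds = np.asarray(gt.truth["cell_seeds"])
        from scipy.spatial import cKDTree

        yy, xx = np.mgrid[0:256, 0:256]
        _, lab = cKDTree(seeds).query(np.column_stack([yy.ravel(), xx.ravel()]))
        lab = lab.reshape(256, 256) + 1
        d = np.linalg.norm(seeds[:, None] - seeds[None, :], axis=2)
        d[np.diag_indices(10)] = np.inf
        a, b = np.unravel_index(np.argmin(d), d.shape)
        boundary = np.zeros((256, 256), bool)
        boundary[:-1] |= lab[:-1] != lab[1:]
        boundary[:, :-1] |= lab[:, :-1] != lab[:, 1:]
        pair_wall = np.zeros_like(boundary)
        pair_wall[:-1] |= (np.minimum(lab[:-1], lab[1:]) == min(a, b) + 1) & \
                          (np.maximum(lab[:-1], lab[1:]) == max(a, b) + 1)
        pair_wall[:, :-1] |= (np.minimum(lab[:, :-1], lab[:, 1:]) == min(a, b) + 1) & \
                             (np.maximum(lab[:, :-1], lab[:, 1:]) == max(a, b) + 1)
        wall_dilated = ndi.binary_dilation(pair_wall, iterations=3)
        img = ndi.gaussian_filter((boundary & ~wall_dilated).astype(float), 1.0) * 100
        cells = segment_cells(img, min_cell_area=64)
        assert cells.n_cells == 9

    def test_no_markers_raises(self, rng):
        noisy = rng.uniform(0, 100, (64, 64))
        with pytest.raises(ValueError):
            segment_cells(noisy, min_cell_area=5000, smoothing_sigma=0.1)

    def test_border_exclusion(self):
        junction, _, _ = gen_comet_field(n_cells=10, comets_per_cell=0,
                                         shape=(256, 256), seed=1)
        kept = segment_cells(junction.pixels, min_cell_area=64,
                             exclude_border_cells=True)
        full = segment_cells(junction.pixels, min_cell_area=64)
        assert kept.n_cells == full.n_cells - len(full.border_touching)
        assert not kept.border_touching


class TestDetectParticles:
    def test_anisotropic_spot_ar(self, rng):
        img = gaussian_spot((64, 64), 32.2, 30.7, 8.0, 4.0, 0.4)
        img += rng.normal(0, 1.0, img.shape).clip(min=0)
        parts = detect_comet_particles(img, one_cell_map((64, 64)), min_area=4)
        assert len(parts) == 1
        assert parts[0].aspect_ratio == pytest.approx(2.0, rel=0.05)
        assert parts[0].centroid == pytest.approx((32.2, 30.7), abs=0.5)

    def test_isotropic_spot_ar_is_one(self):
        img = gaussian_spot((64, 64), 32.0, 32.0, 6.0, 6.0, 0.0)
        parts = detect_comet_particles(img, one_cell_map((64, 64)), min_area=4)
        assert parts[0].aspect_ratio == pytest.approx(1.0, rel=0.03)

    @pytest.mark.parametrize("theta", [0.0, 0.5, 1.0, 1.3])
    def test_ar_rotation_invariance(self, theta):
        # a well-resolved spot keeps the rasterized moment ellipse
        # within 3% of truth at any orientation
        img = gaussian_spot((96, 96), 48.0, 48.0, 12.0, 6.0, theta)
        parts = detect_comet_particles(img, one_cell_map((96, 96)), min_area=4)
        assert parts[0].aspect_ratio == pytest.approx(2.0, rel=0.03)

    def test_intensity_scaling_invariance_with_fixed_mask(self):
        img = gaussian_spot((64, 64), 32.0, 30.0, 8.0, 4.0, 0.7)
        a = detect_comet_particles(img, one_cell_map((64, 64)),
                                   threshold_method="fixed", fixed_threshold=50.0)
        b = detect_comet_particles(img * 3.0, one_cell_map((64, 64)),
                                   threshold_method="fixed", fixed_threshold=150.0)
        assert a[0].aspect_ratio == b[0].aspect_ratio

    def test_min_area_excludes_single_pixel(self):
        img = np.zeros((32, 32))
        img[10, 10] = 100.0
        parts = detect_comet_particles(img, one_cell_map((32, 32)), min_area=4,
                                       threshold_method="fixed", fixed_threshold=50.0)
        assert parts == []

    def test_blank_image_empty_not_error(self):
        assert detect_comet_particles(np.zeros((32, 32)), one_cell_map((32, 32))) == []

    def test_unknown_threshold_method(self):
        with pytest.raises(ValueError):
            detect_comet_particles(np.ones((32, 32)), one_cell_map((32, 32)),
                                   threshold_method="magic")

    def test_particle_on_background_label_discarded(self):
        labels = np.ones((64, 64), np.int32)
        labels[:, 28:36] = 0  # junction band through the centre
        cells = CellLabelMap(labels, 1)
        img = gaussian_spot((64, 64), 32.0, 32.0, 6.0, 3.0, 0.0)
        assert detect_comet_particles(img, cells, min_area=4) == []


class TestAggregation:
    def _particle(self, ar, cell):
        return Particle((0.0, 0.0), 10.0, ar * 2, 2.0, ar, cell)

    def test_mean_of_two(self):
        cells = CellLabelMap(np.ones((4, 4), np.int32), 2)
        out = per_cell_mean_ar([self._particle(1.5, 1), self._particle(2.5, 1)], cells)
        assert len(out) == 1
        assert out[0].mean_ar == pytest.approx(2.0)
        assert out[0].n_comets == 2

    def test_empty_cells_omitted(self):
        cells = CellLabelMap(np.ones((4, 4), np.int32), 2)
        out = per_cell_mean_ar([self._particle(1.7, 2)], cells)
        assert [c.cell_label for c in out] == [2]

    def test_many_cells_match_recomputation(self, rng):
        cells = CellLabelMap(np.ones((4, 4), np.int32), 50)
        particles = []
        expected = {}
        for cell in range(1, 51):
            ars = rng.uniform(1.0, 3.0, int(rng.integers(1, 9)))
            expected[cell] = ars.mean()
            particles += [self._particle(a, cell) for a in ars]
        out = per_cell_mean_ar(particles, cells)
        assert len(out) == 50
        for rec in out:
            assert rec.mean_ar == pytest.approx(expected[rec.cell_label], abs=1e-12)

    def test_unknown_cell_rejected(self):
        cells = CellLabelMap(np.ones((4, 4), np.int32), 1)
        with pytest.raises(ValueError):
            per_cell_mean_ar([self._particle(2.0, 7)], cells)

    def test_condition_summary(self):
        mean, sem, n = condition_summary([1.0, 2.0, 3.0])
        assert (mean, n) == (2.0, 3)
        assert sem == pytest.approx(1 / math.sqrt(3))
        assert condition_summary([2.0, 2.0, 2.0])[1] == 0.0
        with pytest.raises(ValueError):
            condition_summary([1.0])


class TestRecovery:
    def test_condition_mean_ar_recovered(self):
        """End-to-end parameter recovery on a synthetic comet field."""
        from cytoquant.preprocess import upscale

        junction, comet, gt = gen_comet_field(n_cells=10, comets_per_cell=8,
                                              true_ar=2.0, snr=10,
                                              shape=(256, 256), seed=2)
        cells = segment_cells(junction.pixels, min_cell_area=64)
        up = upscale(comet.pixels, 3)
        labels_up = np.kron(cells.labels, np.ones((3, 3), dtype=np.int32))
        cells_up = CellLabelMap(labels_up, cells.n_cells)
        parts = detect_comet_particles(up, cells_up, min_area=4)
        per_cell = per_cell_mean_ar(parts, cells_up)
        mean, _, n = condition_summary([c.mean_ar for c in per_cell])
        assert n >= 8
        assert mean == pytest.approx(2.0, rel=0.05)
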