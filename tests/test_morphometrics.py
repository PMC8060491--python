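"""Segmentation and shape metrics: circularity anchors, recovery, comparisons."""

import math

import numpy as np
import pytest
import scipy.stats
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from vaskit.errors import EmptySegmentationError, PairingError, ParameterError
from vaskit.morphometrics import (
    compare_shapes,
    compute_shape_metrics,
    segment_boundary_image,
)
from vaskit.synth import ShapeSimParams, sample_cell_population, simulate_cell_mosaic


def rasterize_disk(radius, size=None):
    size = size or (2 * radius + 12)
    img = np.zeros((size, size), dtype=np.int32)
    rr, cc = draw_disk((size // 2, size // 2), radius)
    img[rr, cc] = 1
    return img


class TestShapeMetrics:
    def test_large_disk_circularity_is_one(self):
        shapes = compute_shape_metrics(rasterize_disk(200, 512), pixel_size_um=1.0)
        assert shapes[0].circularity_raw == pytest.approx(1.0, abs=0.02)

    def test_square_circularity_is_pi_over_four(self):
        img = np.zeros((260, 260), dtype=np.int32)
        img[30:230, 30:230] = 1
        shapes = compute_shape_metrics(img, pixel_size_um=1.0)
        assert shapes[0].circularity_raw == pytest.approx(math.pi / 4, abs=0.02)

    def test_four_to_one_rectangle_closed_form(self):
        # 4s x s rectangle: circularity = 16*pi/100
        img = np.zeros((120, 440), dtype=np.int32)
        img[10:110, 20:420] = 1
        shapes = compute_shape_metrics(img, pixel_size_um=1.0)
        assert shapes[0].circularity_raw == pytest.approx(16 * math.pi / 100, abs=0.02)

    def test_disk_area_physical_units(self):
        shapes = compute_shape_metrics(rasterize_disk(100), pixel_size_um=0.25)
        assert shapes[0].area_um2 == pytest.approx(math.pi * 25.0**2, rel=0.01)

    def test_circularity_scale_invariant_area_quadruples(self):
        img = rasterize_disk(60)
        s1 = compute_shape_metrics(img, pixel_size_um=1.0)[0]
        s2 = compute_shape_metrics(img, pixel_size_um=2.0)[0]
        assert s2.circularity_raw == pytest.approx(s1.circularity_raw, abs=1e-12)
        assert s2.area_um2 == pytest.approx(4 * s1.area_um2, rel=1e-12)

    def test_circularity_decreases_with_elongation(self):
        area = math.pi * 100**2
        values = []
        for aspect in (1, 2, 3, 4, 5):
            a = math.sqrt(area * aspect / math.pi)
            b = a / aspect
            img = np.zeros((720, 720), dtype=np.int32)
            rr, cc = draw_ellipse(360, 360, a, b, rotation=0.4)
            img[rr, cc] = 1
            values.append(compute_shape_metrics(img, pixel_size_um=1.0)[0].circularity_raw)
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_clamped_circularity_capped_at_one(self):
        s = compute_shape_metrics(rasterize_disk(8), pixel_size_um=1.0)[0]
        assert s.circularity <= 1.0

    def test_empty_labels_rejected(self):
        with pytest.raises(EmptySegmentationError):
            compute_shape_metrics(np.zeros((20, 20), dtype=int), 1.0)


class TestSegmentation:
    def test_mosaic_cells_recovered_with_high_jaccard(self):
        p = ShapeSimParams(n_cells=40, mean_area_um2=30.9, elongation=1.3, seed=3)
        mosaic = simulate_cell_mosaic(p)
        labels = segment_boundary_image(mosaic.boundary_image, pixel_size_um=p.pixel_size_um, min_area_um2=5.0)
        recovered = 0
        for lab in np.unique(mosaic.labels[mosaic.labels > 0]):
            truth_mask = mosaic.labels == lab
            overlap = np.bincount(labels[truth_mask].ravel())
            best = overlap.argmax()
            if best == 0:
                continue
            pred_mask = labels == best
            jaccard = (truth_mask & pred_mask).sum() / (truth_mask | pred_mask).sum()
            recovered += jaccard >= 0.8
        assert recovered / p.n_cells >= 0.95

    def test_blank_image_signals_empty(self):
        with pytest.raises(EmptySegmentationError):
            segment_boundary_image(np.zeros((50, 50)))

    def test_min_area_filter_can_dominate(self):
        mosaic = simulate_cell_mosaic(ShapeSimParams(n_cells=10, seed=1))
        with pytest.raises(EmptySegmentationError):
            segment_boundary_image(
                mosaic.boundary_image, pixel_size_um=mosaic.pixel_size_um, min_area_um2=1e6
            )


class TestCompare:
    def make_shapes(self, areas):
        from vaskit.morphometrics import CellShape

        return [
            CellShape(label=i, area_um2=a, perimeter_um=2 * math.sqrt(math.pi * a), circularity_raw=1.0)
            for i, a in enumerate(areas, 1)
        ]

    def test_identical_groups_no_difference(self):
        g = self.make_shapes([10, 20, 30])
        out = compare_shapes(g, g)
        assert out["area_um2"].test.p_two_tailed == 1.0

    def test_matches_brute_force_oracle(self, rng):
        a = self.make_shapes(rng.uniform(20, 40, 12))
        b = self.make_shapes(rng.uniform(15, 35, 15))
        out = compare_shapes(a, b)
        oracle = scipy.stats.ttest_ind([s.area_um2 for s in a], [s.area_um2 for s in b])
        assert out["area_um2"].test.t_statistic == pytest.approx(oracle.statistic, abs=1e-10)
        assert out["area_um2"].test.p_two_tailed == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_young_old_area_settings_separate(self):
        """Monte-Carlo at the young/old mean-area settings (30.9 vs 23.1 um^2,
        n=100): significant at p < 0.01 in >= 95% of replicates."""
        hits, n_rep = 0, 200
        for seed in range(n_rep):
            young = sample_cell_population(ShapeSimParams(n_cells=100, mean_area_um2=30.9, seed=seed))
            old = sample_cell_population(ShapeSimParams(n_cells=100, mean_area_um2=23.1, seed=10_000 + seed))
            a = self.make_shapes(young["area_um2"])
            b = self.make_shapes(old["area_um2"])
            hits += compare_shapes(a, b)["area_um2"].test.p_two_tailed < 0.01
        assert hits / n_rep >= 0.95

    def test_paired_with_unequal_sizes_rejected(self):
        with pytest.raises(PairingError):
            compare_shapes(self.make_shapes([1, 2, 3]), self.make_shapes([1, 2]), paired=True)

    def test_sem_is_the_reported_spread(self):
        g1 = self.make_shapes([10.0, 20.0, 30.0])
        g2 = self.make_shapes([11.0, 21.0, 31.0])
        out = compare_shapes(g1, g2)
        assert out["area_um2"].spread_convention == "sem"
        assert out["area_um2"].group_a.sem == pytest.approx(10.0 / math.sqrt(3), rel=1e-12)
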