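"""Generators: determinism, ground-truth consistency, closed-form anchors."""

import math

import numpy as np
import pytest

from vaskit.errors import ParameterError, PlacementError
from vaskit.synth import (
    BedOutlinePair,
    FlowSimParams,
    MurrayNetParams,
    ShapeSimParams,
    ellipse_circularity,
    sample_cell_population,
    simulate_bed_outlines,
    simulate_cell_mosaic,
    simulate_murray_network,
    simulate_vessel_movie,
)


class TestVesselMovie:
    def test_zero_flow_zero_noise_frames_identical(self):
        p = FlowSimParams(velocity_profile=0.0, noise_sigma=0.0, n_frames=10, seed=0)
        stack = simulate_vessel_movie(p)
        assert np.array_equal(stack.frames[0], stack.frames[5])
        assert np.array_equal(stack.frames[0], stack.frames[-1])

    def test_same_seed_bit_identical(self):
        p = FlowSimParams(n_frames=12, seed=7)
        s1 = simulate_vessel_movie(p)
        s2 = simulate_vessel_movie(p)
        assert np.array_equal(s1.frames, s2.frames)

    def test_different_seed_differs(self):
        s1 = simulate_vessel_movie(FlowSimParams(n_frames=12, seed=1))
        s2 = simulate_vessel_movie(FlowSimParams(n_frames=12, seed=2))
        assert not np.array_equal(s1.frames, s2.frames)

    def test_default_calibration_matches_acquisition(self):
        p = FlowSimParams()
        assert p.pixel_size_um == 0.313
        assert p.frame_interval_s == 0.177

    def test_single_particle_advances_exactly_by_velocity(self):
        """Brute-force tracking oracle: the dark particle's column advances
        2 px per frame, modulo the periodic segment length."""
        p = FlowSimParams(
            n_frames=40,
            length_px=100,
            particle_density=1.0,  # exactly one particle
            velocity_profile=2.0,
            n_immobile=0,
            noise_sigma=0.0,
            background_gradient=0.0,
            seed=5,
        )
        stack = simulate_vessel_movie(p)
        cols = [int(np.argmin(frame.min(axis=0))) for frame in stack.frames]
        for t in range(len(cols) - 1):
            assert (cols[t + 1] - cols[t]) % p.length_px == 2

    def test_immobile_speckles_stay_fixed(self):
        p = FlowSimParams(
            n_frames=10, particle_density=0.0, n_immobile=4, noise_sigma=0.0, velocity_profile=1.0, seed=3
        )
        stack = simulate_vessel_movie(p)
        assert np.array_equal(stack.frames[0], stack.frames[-1])

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ParameterError):
            FlowSimParams(length_px=0)
        with pytest.raises(ParameterError):
            FlowSimParams(n_frames=1)
        with pytest.raises(ParameterError):
            FlowSimParams(noise_sigma=-0.1)

    def test_velocity_profile_length_checked(self):
        with pytest.raises(ParameterError):
            FlowSimParams(n_frames=10, velocity_profile=tuple(range(4))).velocity_per_frame()


class TestMurrayNetwork:
    def test_child_diameter_closed_form(self):
        net = simulate_murray_network(
            MurrayNetParams(n_levels=2, exponent=3.0, root_diameter_um=60.0, noise_sigma=0.0)
        )
        children = [r for r in net.records if r.vessel_id.startswith("L1")]
        expected = 60.0 * 2 ** (-1.0 / 3.0)  # 47.622...
        assert len(children) == 2
        for child in children:
            assert child.diameter_um == pytest.approx(expected, abs=1e-9)

    def test_flow_conserved_at_every_branch_point(self):
        net = simulate_murray_network(MurrayNetParams(n_levels=4, exponent=2.7, noise_sigma=0.0))
        q = [r.q_flow_um3_s for r in net.records]
        children_of: dict[int, list[int]] = {}
        for parent, child in net.edges:
            children_of.setdefault(parent, []).append(child)
        for parent, kids in children_of.items():
            assert sum(q[k] for k in kids) == pytest.approx(q[parent], rel=1e-12)

    def test_velocity_consistent_with_flow_and_area(self):
        net = simulate_murray_network(MurrayNetParams(n_levels=3, noise_sigma=0.0))
        for r in net.records:
            area = math.pi * r.diameter_um**2 / 4.0
            assert r.q_flow_um3_s == pytest.approx(r.v_max_um_s * area, rel=1e-12)

    def test_deterministic_given_seed(self):
        p = MurrayNetParams(noise_sigma=0.05, seed=9)
        n1 = simulate_murray_network(p)
        n2 = simulate_murray_network(p)
        assert [r.diameter_um for r in n1.records] == [r.diameter_um for r in n2.records]

    def test_rejects_non_positive_exponent(self):
        with pytest.raises(ParameterError):
            MurrayNetParams(exponent=0.0)


class TestCellMosaic:
    def test_disks_have_unit_ground_truth_circularity(self):
        p = ShapeSimParams(n_cells=5, elongation=1.0, seed=1)
        truth = sample_cell_population(p)
        assert np.allclose(truth["circularity"], 1.0, atol=1e-12)

    def test_ellipse_circularity_closed_form(self):
        # circle exact; strongly elongated ellipse well below 1
        assert ellipse_circularity(1.0) == pytest.approx(1.0, abs=1e-12)
        assert ellipse_circularity(4.0) < 0.6

    def test_labels_non_overlapping_and_match_count(self):
        p = ShapeSimParams(n_cells=30, seed=4)
        mosaic = simulate_cell_mosaic(p)
        ids = np.unique(mosaic.labels[mosaic.labels > 0])
        assert ids.size == 30
        # pixel areas close to the intended areas
        areas_px = np.bincount(mosaic.labels.ravel())[1:]
        areas_um2 = np.sort(areas_px * p.pixel_size_um**2)
        assert np.allclose(areas_um2, np.sort(mosaic.truth["area_um2"]), rtol=0.15)

    def test_label_areas_partition_image(self):
        mosaic = simulate_cell_mosaic(ShapeSimParams(n_cells=10, seed=2))
        counts = np.bincount(mosaic.labels.ravel())
        assert counts.sum() == mosaic.labels.size

    def test_rejects_zero_cells(self):
        with pytest.raises(ParameterError):
            ShapeSimParams(n_cells=0)

    def test_impossible_packing_raises_placement_error(self):
        with pytest.raises(PlacementError):
            simulate_cell_mosaic(
                ShapeSimParams(n_cells=50, mean_area_um2=500.0, area_cv=0.0, image_size_px=64,
                               pixel_size_um=0.25, seed=0, max_retries_per_cell=20)
            )


class TestBedOutlines:
    @pytest.mark.parametrize("fraction,expected", [(0.0, 0.0), (1.0, 100.0), (0.964, 96.4)])
    def test_requested_loss_fraction_reproduced_exactly(self, fraction, expected):
        pair = simulate_bed_outlines(fraction, seed=3)
        assert pair.percent_regression == pytest.approx(expected, abs=1e-9)

    def test_polygon_perimeters_define_the_scalars(self):
        from vaskit.regression import polygon_perimeter

        pair = simulate_bed_outlines(0.5, seed=1)
        assert pair.control.p_a == pytest.approx(
            polygon_perimeter(pair.control_polygons["ampullae"]), abs=1e-9
        )
        assert pair.control.p_b == pytest.approx(
            polygon_perimeter(pair.control_polygons["body"]), abs=1e-9
        )

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            simulate_bed_outlines(1.2)
        with pytest.raises(ParameterError):
            simulate_bed_outlines(-0.1)
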