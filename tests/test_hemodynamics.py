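"""Diameter measurement, volumetric flow and the branching-exponent fit."""

import math

import numpy as np
import pytest

from conftest import cross_roi
from vaskit.errors import FitError, MeasurementError, ParameterError
from vaskit.hemodynamics import (
    VesselRecord,
    compare_diameter_groups,
    compare_velocity_groups,
    fit_branching_exponent,
    measure_diameter,
    volumetric_flow,
)
from vaskit.kymo import LineRoi
from vaskit.synth import FlowSimParams, MurrayNetParams, simulate_murray_network, simulate_vessel_movie


def records_from_diameters(diams, group=""):
    return [
        VesselRecord(vessel_id=f"v{i}", diameter_um=d, v_max_um_s=100.0,
                     q_flow_um3_s=100.0 * math.pi * d**2 / 4, age_group=group)
        for i, d in enumerate(diams)
    ]


class TestDiameter:
    def test_manual_endpoint_mode_is_a_ruler(self):
        roi = LineRoi(points=[(0, 0), (100, 0)], kind="cross")
        assert measure_diameter(np.zeros((10, 120)), roi, 0.313, method="endpoints") == pytest.approx(31.3)

    def test_fwhm_recovers_rendered_lumen_width(self):
        p = FlowSimParams(velocity_profile=2.0, width_px=40, n_frames=256, particle_density=16, seed=6)
        stack = simulate_vessel_movie(p)
        d = measure_diameter(stack.min_projection(), cross_roi(stack, x=150), p.pixel_size_um)
        assert d == pytest.approx(40 * 0.313, abs=1.0 * 0.313)

    def test_fwhm_invariant_to_affine_intensity_transform(self):
        p = FlowSimParams(velocity_profile=2.0, width_px=40, n_frames=120, seed=2)
        stack = simulate_vessel_movie(p)
        proj = stack.min_projection()
        roi = cross_roi(stack)
        d0 = measure_diameter(proj, roi, p.pixel_size_um)
        d1 = measure_diameter(5.0 * proj + 17.0, roi, p.pixel_size_um)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_flat_profile_is_a_measurement_failure(self):
        roi = LineRoi(points=[(5, 1), (5, 18)], kind="cross")
        with pytest.raises(MeasurementError):
            measure_diameter(np.ones((20, 10)), roi, 1.0)

    def test_axial_roi_rejected(self):
        roi = LineRoi(points=[(0, 5), (9, 5)], kind="axial")
        with pytest.raises(ParameterError):
            measure_diameter(np.zeros((10, 10)), roi, 1.0)


class TestVolumetricFlow:
    def test_zero_velocity_zero_flow(self):
        assert volumetric_flow(0.0, 20.0) == 0.0

    def test_plug_closed_form(self):
        # v=100, d=20 -> Q = 100 * pi * 100 = 31,416
        assert volumetric_flow(100.0, 20.0, "plug") == pytest.approx(100 * math.pi * 100, rel=1e-12)

    def test_poiseuille_is_half_of_plug(self):
        assert volumetric_flow(80.0, 33.0, "poiseuille") == pytest.approx(
            volumetric_flow(80.0, 33.0, "plug") / 2.0, rel=1e-12
        )

    def test_unknown_model_rejected(self):
        with pytest.raises(ParameterError):
            volumetric_flow(1.0, 1.0, "parabolic-ish")


class TestBranchingFit:
    def test_exact_cubic_data(self):
        recs = [
            VesselRecord(f"v{i}", d, v_max_um_s=d, q_flow_um3_s=2.5 * d**3)
            for i, d in enumerate([10, 20, 30, 40, 55])
        ]
        fit = fit_branching_exponent(recs)
        assert fit.exponent == pytest.approx(3.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_prefactor_independence(self):
        recs = records_from_diameters([12, 25, 33, 47])
        scaled = [
            VesselRecord(r.vessel_id, r.diameter_um, r.v_max_um_s, r.q_flow_um3_s * 7.3)
            for r in recs
        ]
        f1, f2 = fit_branching_exponent(recs), fit_branching_exponent(scaled)
        assert f1.exponent == pytest.approx(f2.exponent, abs=1e-12)

    def test_noiseless_murray_tree_recovers_exponent_exactly(self):
        for n in (2.8, 3.0):
            net = simulate_murray_network(MurrayNetParams(n_levels=5, exponent=n, noise_sigma=0.0))
            fit = fit_branching_exponent(net.records)
            assert fit.exponent == pytest.approx(n, abs=1e-6)

    def test_noisy_murray_tree_recovery(self):
        estimates = []
        for seed in range(10):
            net = simulate_murray_network(MurrayNetParams(n_levels=5, exponent=2.8, noise_sigma=0.05, seed=seed))
            estimates.append(fit_branching_exponent(net.records).exponent)
        assert abs(float(np.median(estimates)) - 2.8) < 0.15

    def test_non_positive_records_filtered_with_warning(self):
        recs = records_from_diameters([10, 20, 30, 40])
        bad = VesselRecord("z", 15.0, 0.0, 0.0)
        with pytest.warns(UserWarning):
            fit = fit_branching_exponent(recs + [bad])
        assert fit.n_vessels == 4

    def test_too_few_records_is_a_fit_error(self):
        with pytest.raises(FitError):
            fit_branching_exponent(records_from_diameters([10, 20]))


class TestGroupComparisons:
    def test_identical_groups(self):
        recs = records_from_diameters([30, 40, 50])
        cmp = compare_diameter_groups(recs, recs)
        assert cmp.test.t_statistic == 0.0
        assert cmp.test.p_two_tailed == 1.0

    def test_published_group_parameters_give_significant_difference(self):
        """Monte-Carlo: groups drawn at the young/old diameter summary
        statistics (49.6 +/- 10.4, n=55 vs 37.3 +/- 13.1, n=64) separate at
        p < 1e-4 at the rate a noncentral-t power oracle predicts (~0.94)."""
        import scipy.stats as ss

        n1, n2, sd1, sd2, diff = 55, 64, 10.4, 13.1, 49.6 - 37.3
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        ncp = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        crit = ss.t.isf(1e-4 / 2, df)
        power = ss.nct.sf(crit, df, ncp) + ss.nct.cdf(-crit, df, ncp)

        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            young = np.clip(rng.normal(49.6, 10.4, n1), 0.5, None)
            old = np.clip(rng.normal(37.3, 13.1, n2), 0.5, None)
            cmp = compare_diameter_groups(records_from_diameters(young), records_from_diameters(old))
            hits += cmp.test.p_two_tailed < 1e-4
        rate = hits / n_rep
        assert rate > 0.9
        assert abs(rate - power) < 0.03

    def test_velocity_band_restriction(self):
        young = records_from_diameters([26, 28, 30, 34, 60])
        old = records_from_diameters([25, 27, 33, 34.9, 80])
        cmp = compare_velocity_groups(young, old, diameter_band=(25, 35))
        assert cmp.group_a.n == 4
        assert cmp.group_b.n == 4  # 35 is excluded: band is [lo, hi)

    def test_empty_band_signals(self):
        young = records_from_diameters([60, 70, 80])
        old = records_from_diameters([55, 65, 75])
        with pytest.raises(MeasurementError):
            compare_velocity_groups(young, old, diameter_band=(25, 35))
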