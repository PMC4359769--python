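import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stemkin as sk
from stemkin.arrival_velocity import (
    METHOD_HALF_HEIGHT,
    convert_units,
    fit_velocity,
    half_height_arrival_time,
    half_height_upper_bound,
    mean_arrival_time,
    trapping_per_length,
)
from stemkin.exceptions import DegenerateFitError, UnfittableCurveError
from stemkin.tac_data import rebase_to_administration


def triangle():
    """Rise 0->1 over [0, 300], fall 1->0 over [300, 600]."""
    times = np.array([0.0, 150.0, 300.0, 450.0, 600.0])
    g = np.array([0.0, 0.5, 1.0, 0.5, 0.0])
    return times, g


class TestUpperBound:
    def test_triangle_half_height(self):
        assert half_height_upper_bound(triangle()) == pytest.approx(450.0)

    def test_monotone_rising_falls_back_to_last_time(self):
        times = np.linspace(0, 1000, 11)
        assert half_height_upper_bound((times, times / 1000.0)) == 1000.0

    def test_no_positive_maximum_rejected(self):
        with pytest.raises(UnfittableCurveError):
            half_height_upper_bound((np.array([0.0, 1.0]), np.array([-1.0, 0.0])))

    def test_synthetic_free_curve_matches_analytic_crossing(self, mean_truth):
        # one frame (60 s) tolerance against the dense half-crossing
        plant = sk.observe_plant(mean_truth)
        curve = rebase_to_administration(plant.curves[3], 60.0)
        fit = sk.solve_trapping_rate(curve, 3300.0)
        ub = half_height_upper_bound((curve.mid_time, fit.free))
        dense_t = np.arange(0.0, 3000.0, 0.05)
        g = sk.free_curve_at_position(mean_truth, curve.position_mm, dense_t)
        pk = g.argmax()
        ub_true = dense_t[pk + np.argmax(g[pk:] < 0.5 * g.max())]
        assert abs(ub - ub_true) < 60.0


class TestMeanArrivalTime:
    def test_rectangle_centroid(self):
        times = np.arange(0.0, 250.0, 0.5)
        g = ((times >= 100.0) & (times <= 200.0)).astype(float)
        assert mean_arrival_time((times, g), 200.0) == pytest.approx(150.0, abs=1.0)

    def test_symmetric_triangle_untruncated(self):
        assert mean_arrival_time(triangle(), np.inf) == pytest.approx(300.0)

    def test_truncated_triangle_matches_dense_quadrature(self):
        # oracle: brute-force quadrature of the same geometry at dt = 0.01 s;
        # the triangle is sampled at 1 s so the t*G moment is well resolved
        t = np.arange(0.0, 450.0001, 0.01)
        g = np.where(t <= 300.0, t / 300.0, 2.0 - t / 300.0)
        oracle = np.trapezoid(t * g, t) / np.trapezoid(g, t)
        times = np.arange(0.0, 601.0, 1.0)
        curve = np.where(times <= 300.0, times / 300.0, 2.0 - times / 300.0)
        assert mean_arrival_time((times, curve), 450.0) == pytest.approx(oracle, rel=1e-5)

    def test_zero_mass_below_bound_rejected(self):
        times, g = triangle()
        with pytest.raises(UnfittableCurveError):
            mean_arrival_time((times, 0.0 * g), 450.0)

    @given(shift=st.floats(10.0, 500.0))
    def test_translation_equivariance(self, shift):
        times, g = triangle()
        t0 = mean_arrival_time((times, g), 450.0)
        t1 = mean_arrival_time((times + shift, g), 450.0 + shift)
        assert t1 == pytest.approx(t0 + shift, abs=1e-9)

    @given(scale=st.floats(1e-6, 1e6))
    def test_scale_invariance(self, scale):
        times, g = triangle()
        assert mean_arrival_time((times, g * scale), 450.0) == pytest.approx(
            mean_arrival_time((times, g), 450.0), rel=1e-12
        )

    def test_truncation_monotone_for_unimodal_curve(self):
        times, g = triangle()
        ubs = [200.0, 300.0, 450.0, 600.0]
        mats = [mean_arrival_time((times, g), ub) for ub in ubs]
        assert mats == sorted(mats)


class TestHalfHeightArrival:
    def test_rising_triangle(self):
        assert half_height_arrival_time(triangle()) == pytest.approx(150.0)

    def test_rectangle_edge_within_one_step(self):
        times = np.arange(0.0, 250.0, 10.0)
        g = ((times >= 100.0) & (times <= 200.0)).astype(float)
        assert abs(half_height_arrival_time((times, g)) - 100.0) <= 10.0

    def test_two_positions_separated_by_transit_time(self, mean_truth):
        dense_t = np.arange(0.0, 2000.0, 0.1)
        x1, x2 = 10.0, 25.0
        t1 = half_height_arrival_time((dense_t, sk.free_curve_at_position(mean_truth, x1, dense_t)))
        t2 = half_height_arrival_time((dense_t, sk.free_curve_at_position(mean_truth, x2, dense_t)))
        assert t2 - t1 == pytest.approx((x2 - x1) / mean_truth.velocity_mm_s, rel=1e-3)


class TestVelocityFit:
    def test_exact_line(self):
        est = [
            sk.ArrivalEstimate("a", 10.0, 100.0),
            sk.ArrivalEstimate("b", 20.0, 200.0),
            sk.ArrivalEstimate("c", 30.0, 300.0),
        ]
        v, intercept, r2 = fit_velocity(est)
        assert v == pytest.approx(0.1)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_two_points_interpolating_slope(self):
        est = [sk.ArrivalEstimate("a", 5.0, 50.0), sk.ArrivalEstimate("b", 8.0, 110.0)]
        v, _, _ = fit_velocity(est)
        assert v == pytest.approx(3.0 / 60.0)

    def test_identical_times_rejected(self):
        est = [sk.ArrivalEstimate("a", 5.0, 50.0), sk.ArrivalEstimate("b", 8.0, 50.0)]
        with pytest.raises(DegenerateFitError):
            fit_velocity(est)

    def test_noise_free_synthetic_velocity(self, mean_truth, clean_result):
        assert clean_result.velocity_mm_s == pytest.approx(
            mean_truth.velocity_mm_s, rel=0.02
        )


class TestTrappingPerLength:
    # printed per-plant (sv, V) pairs and the per-length ratios they imply
    @pytest.mark.parametrize(
        "sv,v,expected",
        [(0.000287, 0.326, 0.00088), (0.000280, 0.214, 0.00131), (0.0, 0.4, 0.0)],
    )
    def test_ratio(self, sv, v, expected):
        assert round(trapping_per_length(sv, v), 5) == expected

    def test_nonpositive_velocity_rejected(self):
        with pytest.raises(ValueError):
            trapping_per_length(1e-4, 0.0)


class TestUnitConversions:
    @pytest.mark.parametrize(
        "value,from_unit,to_unit,expected",
        [
            (0.368, "mm/s", "cm/min", 2.208),
            (0.000253, "1/s", "1/min", 0.01518),
            (0.00084, "1/mm", "1/cm", 0.0084),
            (0.015, "fraction", "percent", 1.5),
        ],
    )
    def test_forward(self, value, from_unit, to_unit, expected):
        assert convert_units(value, from_unit, to_unit) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pair", [("1/s", "1/min"), ("mm/s", "cm/min"), ("1/mm", "1/cm"), ("fraction", "percent")]
    )
    def test_round_trip(self, pair):
        x = 0.123456
        assert convert_units(convert_units(x, *pair), pair[1], pair[0]) == pytest.approx(x, rel=1e-15)

    def test_unsupported_pair_rejected(self):
        with pytest.raises(ValueError):
            convert_units(1.0, "mm/s", "1/min")


class TestMethodAgreement:
    def test_leading_edge_velocity_comparable_noise_free(self, clean_plant, clean_result):
        alt = sk.analyze_plant(
            clean_plant.curves, clean_plant.manifest, arrival_method=METHOD_HALF_HEIGHT
        )
        rel = abs(alt.velocity_mm_s - clean_result.velocity_mm_s) / clean_result.velocity_mm_s
        assert rel < 0.40
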