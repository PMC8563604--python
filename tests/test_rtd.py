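import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flowbed import rtd, simulate
from flowbed.exceptions import DataInconsistencyError, SignalQualityError


class TestDimensionlessNumbers:
    @pytest.mark.parametrize(
        "area,perimeter,expected",
        [
            (math.pi * 2.0**2 / 4.0, math.pi * 2.0, 2.0),  # circle of diameter 2
            (3.0**2, 4 * 3.0, 3.0),  # square of side 3
            (3 * math.sqrt(3) / 2 * 2.0**2, 6 * 2.0, math.sqrt(3) * 2.0),  # hexagon
        ],
    )
    def test_hydraulic_diameter_closed_forms(self, area, perimeter, expected):
        assert rtd.hydraulic_diameter(area, perimeter) == pytest.approx(expected)

    def test_hydraulic_diameter_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            rtd.hydraulic_diameter(0.0, 1.0)

    def test_reynolds_arithmetic(self):
        water = rtd.FluidProperties(1000.0, 1e-3)
        assert rtd.reynolds(water, 0.01, 0.001) == pytest.approx(10.0)
        assert rtd.reynolds(water, 0.02, 0.001) == pytest.approx(20.0)

    def test_reynolds_worked_example(self):
        fluid = rtd.FluidProperties(998.0, 1.2e-3)
        assert rtd.reynolds(fluid, 0.005, 5e-4) == pytest.approx(2.0792, rel=1e-4)


class TestInsertGeometry:
    def test_builtin_catalogue_is_consistent(self, inserts):
        assert set(inserts) == {"HC1", "HC2", "HC3", "CL1", "CL2", "CL3"}
        for geom in inserts.values():
            assert geom.length == 39.8
            assert geom.flow_area > 0

    def test_inconsistent_area_ratio_rejected(self):
        with pytest.raises(Exception, match="area-to-volume"):
            rtd.InsertGeometry(
                name="bad",
                family="HC",
                hydraulic_diameter=1.0,
                internal_volume=100.0,
                length=10.0,
                internal_area=500.0,
                area_to_volume=9.0,
            )


class TestNormalizeStep:
    def test_ideal_step(self):
        s = np.r_[np.zeros(50), np.ones(50)]
        f = rtd.normalize_step(s)
        assert np.all(f[:50] == 0.0)
        assert np.all(f[-40:] == 1.0)

    def test_step_down_flag_recovers_step_up(self):
        up = np.r_[np.zeros(50), np.ones(50)]
        down = 5.0 - 2.0 * up
        np.testing.assert_allclose(
            rtd.normalize_step(down, step_down=True), rtd.normalize_step(up)
        )

    def test_flat_signal_is_rejected(self):
        with pytest.raises(SignalQualityError):
            rtd.normalize_step(np.full(100, 3.0))

    def test_noise_only_signal_is_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(SignalQualityError):
            rtd.normalize_step(1.0 + 0.01 * rng.standard_normal(200))

    def test_noisy_step_tracks_analytic_f(self):
        step = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.005, seed=0)
        clean = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.0)
        f = rtd.normalize_step(step.outlet)
        f_true = rtd.normalize_step(clean.outlet)
        assert np.max(np.abs(f - f_true)) < 0.02

    def test_clipped_f_is_bounded_and_monotone_when_noise_free(self):
        clean = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.0)
        f = rtd.normalize_step(clean.outlet)
        assert np.all((f >= 0.0) & (f <= 1.0))
        assert np.all(np.diff(f) >= -1e-9)


class TestFToE:
    def test_linear_ramp_gives_uniform_density(self):
        t = np.linspace(0.0, 3.0, 301)
        f = np.clip(t / 2.0, 0.0, 1.0)
        e = rtd.f_to_e(f, t, smooth_window=0)
        inside = (t > 0.05) & (t < 1.95)
        np.testing.assert_allclose(e[inside], 0.5, atol=1e-6)
        assert np.all(e[t > 2.1] == 0.0)

    def test_unit_area_contract(self):
        t = np.linspace(0.0, 10.0, 500)
        f = 1.0 - np.exp(-t)
        e = rtd.f_to_e(f, t)
        assert np.trapezoid(e, t) == pytest.approx(1.0, abs=1e-3)

    def test_recovers_open_open_density(self):
        # differentiate an analytic open-open F back into E
        bo, t_mean = 20.0, 30.0
        t = np.linspace(0.0, 12 * t_mean, 2000)
        e_true = simulate.open_open_E(t / t_mean, bo) / t_mean
        e_true /= np.trapezoid(e_true, t)
        from scipy.integrate import cumulative_trapezoid

        f = cumulative_trapezoid(e_true, t, initial=0.0)
        e = rtd.f_to_e(f, t)
        assert np.max(np.abs(e - e_true)) / np.max(e_true) < 0.02

    def test_too_few_samples_rejected(self):
        with pytest.raises(Exception):
            rtd.f_to_e([0, 0.5, 1.0], [0, 1, 2])


class TestMoments:
    def test_uniform_density_closed_form(self):
        t = np.linspace(0.0, 2.0, 2001)
        e = np.full_like(t, 0.5)
        tm, var = rtd.moments(e, t)
        assert tm == pytest.approx(1.0, rel=1e-6)
        assert var == pytest.approx(1.0 / 3.0, rel=1e-5)

    def test_narrow_pulse_localizes(self):
        t = np.linspace(0.0, 10.0, 10001)
        e = np.exp(-0.5 * ((t - 4.0) / 0.01) ** 2)
        tm, var = rtd.moments(e, t)
        assert tm == pytest.approx(4.0, abs=1e-6)
        assert var < 1e-3

    def test_exponential_cstr_variance(self):
        tau = 2.0
        t = np.linspace(0.0, 12 * tau, 10_000)
        e = np.exp(-t / tau) / tau
        tm, var = rtd.moments(e, t)
        assert var / tm**2 == pytest.approx(1.0, rel=0.02)


class TestCorrectMoments:
    def test_zero_inlet_is_identity(self):
        assert rtd.correct_moments((10.0, 4.0), (0.0, 0.0)) == (10.0, 4.0)

    def test_elementwise_subtraction(self):
        assert rtd.correct_moments((10.0, 4.0), (3.0, 1.0)) == (7.0, 3.0)

    def test_negative_difference_rejected(self):
        with pytest.raises(DataInconsistencyError):
            rtd.correct_moments((3.0, 1.0), (10.0, 4.0))

    def test_additivity_of_convolved_devices(self):
        # composite minus first device equals the second device's own moments
        t = np.linspace(0.0, 240.0, 4000)
        dt = t[1] - t[0]
        e1 = simulate.open_open_E(t / 10.0, 20.0) / 10.0
        e2 = simulate.open_open_E(t / 20.0, 10.0) / 20.0
        e1 /= np.trapezoid(e1, t)
        e2 /= np.trapezoid(e2, t)
        composite = np.convolve(e1, e2)[: t.size] * dt
        corrected = rtd.correct_moments(
            rtd.moments(composite, t), rtd.moments(e1, t)
        )
        expected = rtd.moments(e2, t)
        assert corrected[0] == pytest.approx(expected[0], rel=0.02)
        assert corrected[1] == pytest.approx(expected[1], rel=0.02)


class TestOpenOpenInversion:
    @pytest.mark.parametrize("sigma,expected", [(3.0, 2.0), (0.0208, 100.0)])
    def test_known_variance_pairs(self, sigma, expected):
        assert rtd.bodenstein_from_variance(sigma) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("bo", [0.5, 1.0, 10.0, 500.0])
    def test_round_trip_is_exact(self, bo):
        s = rtd.sigma_theta_from_bodenstein(bo)
        assert rtd.bodenstein_from_variance(s) == pytest.approx(bo, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=1e4))
    def test_round_trip_property(self, bo):
        s = rtd.sigma_theta_from_bodenstein(bo)
        assert rtd.bodenstein_from_variance(s) == pytest.approx(bo, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rtd.bodenstein_from_variance(0.0)
        with pytest.raises(ValueError):
            rtd.sigma_theta_from_bodenstein(-1.0)

    @given(st.floats(min_value=0.5, max_value=500.0))
    def test_measured_moment_relation_inverts_the_open_vessel_shift(self, bo):
        # measured mean tau*(1+2/Bo) and variance tau^2*(2/Bo+8/Bo^2)
        tau = 30.0
        t_mean = tau * (1.0 + 2.0 / bo)
        var = tau**2 * rtd.sigma_theta_from_bodenstein(bo)
        assert rtd.bodenstein_from_moments(t_mean, var) == pytest.approx(bo, rel=1e-9)

    def test_moment_relation_out_of_range(self):
        with pytest.raises(ValueError):
            rtd.bodenstein_from_moments(1.0, 2.5)


class TestAnalyzeRTD:
    def test_recovers_bodenstein_from_noisy_pair(self, hc3, ethanol):
        step = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.005, seed=1)
        res = rtd.analyze_rtd(
            step.time, step.inlet, step.outlet, hc3, ethanol, 1.0, keep_curves=False
        )
        assert res.bodenstein == pytest.approx(20.0, rel=0.05)

    def test_identical_series_flagged_above_range(self, hc3, ethanol):
        step = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.0)
        res = rtd.analyze_rtd(
            step.time, step.outlet, step.outlet, hc3, ethanol, 1.0, keep_curves=False
        )
        assert res.above_range
        assert math.isinf(res.bodenstein)
        assert res.axial_dispersion == 0.0

    def test_ordering_preserved_under_noise(self, hc3, ethanol):
        recovered = []
        for bo in (5.0, 80.0):
            step = simulate.simulate_tracer_step(bo, 30.0, noise_rel=0.005, seed=3)
            res = rtd.analyze_rtd(
                step.time, step.inlet, step.outlet, hc3, ethanol, 1.0, keep_curves=False
            )
            recovered.append(res.bodenstein)
        assert recovered[0] < recovered[1]

    def test_dispersion_velocity_consistency(self, hc3, ethanol):
        step = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.0)
        res = rtd.analyze_rtd(step.time, step.inlet, step.outlet, hc3, ethanol, 1.5)
        u = res.superficial_velocity
        assert res.axial_dispersion == pytest.approx(
            u * hc3.length * 1e-3 / res.bodenstein, rel=1e-9
        )
        expected_u = (1.5 * 1e-6 / 60.0) / (hc3.flow_area * 1e-6)
        assert u == pytest.approx(expected_u, rel=1e-12)
        assert res.curves is not None
        assert np.trapezoid(res.curves.e_outlet, res.curves.time) == pytest.approx(
            1.0, abs=1e-3
        )
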