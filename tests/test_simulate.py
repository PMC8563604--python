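import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flowbed import doe, metrics, rtd, simulate


class TestOpenOpenDensity:
    def test_unit_area(self):
        theta = np.linspace(1e-6, 12.0, 20_000)
        e = simulate.open_open_E(theta, 20.0)
        assert np.trapezoid(e, theta) == pytest.approx(1.0, abs=1e-3)

    def test_variance_matches_closed_form(self):
        # numeric variance about theta = 1+2/Bo equals 2/Bo + 8/Bo^2
        theta = np.linspace(1e-6, 20.0, 100_000)
        e = simulate.open_open_E(theta, 20.0)
        e /= np.trapezoid(e, theta)
        mean = np.trapezoid(theta * e, theta)
        var = np.trapezoid((theta - mean) ** 2 * e, theta)
        assert var == pytest.approx(rtd.sigma_theta_from_bodenstein(20.0), rel=0.02)

    def test_high_bo_concentrates_near_unity(self):
        theta = np.linspace(1e-6, 5.0, 50_000)
        e = simulate.open_open_E(theta, 1000.0)
        e /= np.trapezoid(e, theta)
        mask = (theta >= 0.9) & (theta <= 1.1)
        assert np.trapezoid(e[mask], theta[mask]) >= 0.85

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            simulate.open_open_E(1.0, 0.0)
        with pytest.raises(ValueError):
            simulate.open_open_E(-1.0, 20.0)


class TestTracerStep:
    def test_same_seed_bit_identical(self):
        a = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.005, seed=5)
        b = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.005, seed=5)
        np.testing.assert_array_equal(a.inlet, b.inlet)
        np.testing.assert_array_equal(a.outlet, b.outlet)

    def test_plateaus_agree(self):
        step = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.0)
        assert step.outlet[-1] == pytest.approx(step.inlet[-1], rel=1e-3)

    def test_noise_free_self_consistency(self, hc3, ethanol):
        step = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.0)
        res = rtd.analyze_rtd(
            step.time, step.inlet, step.outlet, hc3, ethanol, 1.0, keep_curves=False
        )
        assert res.bodenstein == pytest.approx(20.0, rel=0.02)
        assert res.mean_residence_time == pytest.approx(30.0 * (1 + 2 / 20.0), rel=0.02)

    def test_records_round_trip_through_log_format(self, tmp_path):
        from flowbed import io_formats

        step = simulate.simulate_tracer_step(20.0, 30.0, noise_rel=0.005, seed=0)
        path = tmp_path / "pair.log"
        io_formats.write_tracer_log(step.to_records(), path)
        t, s_in, s_out = io_formats.tracer_arrays(io_formats.read_tracer_log(path))
        np.testing.assert_array_equal(t, step.time)
        np.testing.assert_array_equal(s_out, step.outlet)


class TestTemperatureProfile:
    def test_peak_at_optimum(self):
        kin = simulate.KineticParams()
        assert simulate.vmax_at_temperature(kin.t_opt, kin) == kin.vmax_ref

    def test_symmetry(self):
        kin = simulate.KineticParams()
        assert simulate.vmax_at_temperature(kin.t_opt + 3.0, kin) == pytest.approx(
            simulate.vmax_at_temperature(kin.t_opt - 3.0, kin)
        )

    def test_worked_value(self):
        kin = simulate.KineticParams(t_opt=30.0, t_width=6.0)
        assert simulate.vmax_at_temperature(25.0, kin) == pytest.approx(
            0.7066 * kin.vmax_ref, rel=1e-4
        )


class TestCascade:
    def test_zero_rate_passes_feed_through(self):
        kin = simulate.KineticParams(vmax_ref=1e-12, km=0.5, n_tanks=5)
        sub, prod = simulate.cstr_cascade_outlet(2.0, 10.0, kin)
        assert sub == pytest.approx(2.0, rel=1e-9)
        assert prod == pytest.approx(0.0, abs=1e-9)

    def test_single_tank_first_order_closed_form(self):
        # Km >> c0: rate ~ k*c with k = Vmax/Km; CSTR conversion = k*tau/(1+k*tau)
        vmax, km = 100.0, 1000.0
        k = vmax / km
        kin = simulate.KineticParams(vmax_ref=vmax, km=km, n_tanks=1)
        tau, c0 = 10.0, 1e-4
        sub, prod = simulate.cstr_cascade_outlet(c0, tau, kin)
        expected = k * tau / (1.0 + k * tau)
        assert prod / c0 == pytest.approx(expected, rel=1e-6)

    def test_many_tanks_approach_plug_flow(self):
        vmax, km = 100.0, 1000.0
        k = vmax / km
        kin = simulate.KineticParams(vmax_ref=vmax, km=km, n_tanks=200)
        tau, c0 = 10.0, 1e-4
        _, prod = simulate.cstr_cascade_outlet(c0, tau, kin)
        assert prod / c0 == pytest.approx(1.0 - math.exp(-k * tau), rel=5e-3)

    @given(
        st.floats(min_value=0.05, max_value=5.0),
        st.floats(min_value=1.0, max_value=200.0),
        st.integers(min_value=1, max_value=30),
    )
    def test_mass_balance_exact(self, c0, tau, n_tanks):
        kin = simulate.KineticParams(vmax_ref=0.05, km=0.5, n_tanks=n_tanks)
        sub, prod = simulate.cstr_cascade_outlet(c0, tau, kin)
        assert sub + prod == pytest.approx(c0, rel=1e-12)
        assert 0.0 <= sub <= c0

    def test_monotone_in_residence_time_and_rate(self):
        kin = simulate.KineticParams(vmax_ref=0.02, km=0.5, n_tanks=8)
        taus = np.linspace(1.0, 120.0, 40)
        subs = np.array([simulate.cstr_cascade_outlet(1.0, t, kin)[0] for t in taus])
        assert np.all(np.diff(subs) < 0)
        vmaxes = np.linspace(0.001, 0.1, 30)
        subs_v = np.array(
            [
                simulate.cstr_cascade_outlet(
                    1.0, 20.0, simulate.KineticParams(vmax_ref=v, km=0.5, n_tanks=8)
                )[0]
                for v in vmaxes
            ]
        )
        assert np.all(np.diff(subs_v) < 0)


class TestTankCountHeuristic:
    def test_matches_inverse_variance(self):
        # Bo = 20 -> sigma_theta^2 = 0.12 -> n ~ 8
        assert simulate.n_tanks_for_bodenstein(20.0) == 8

    def test_never_below_one(self):
        assert simulate.n_tanks_for_bodenstein(0.5) == 1


class TestSimulateExperiment:
    @pytest.fixture
    def reactor(self, hc3):
        return simulate.VirtualReactor(
            geometry=hc3, kinetics=simulate.KineticParams(seed=11)
        )

    @pytest.fixture
    def points(self, space):
        return doe.generate_ccd(doe.subregion_first(space))

    def test_noise_free_is_deterministic_function_of_point(self, reactor, points):
        a = simulate.simulate_experiment(points[2], reactor, noise_rel=0.0)
        b = simulate.simulate_experiment(points[2], reactor, noise_rel=0.0)
        assert a == b

    def test_seeded_noise_reproducible_and_run_dependent(self, reactor, points):
        a = simulate.simulate_experiment(points[1], reactor)
        b = simulate.simulate_experiment(points[1], reactor)
        other = simulate.simulate_experiment(points[2], reactor)
        assert a == b
        assert a.c_substrate != other.c_substrate

    def test_conversion_decreases_with_flowrate(self, reactor, space):
        sub = doe.subregion_first(space)
        conv = []
        for fr in np.linspace(0.47, 1.73, 8):
            point = doe.DesignPoint(
                factors=space.names,
                coded=(0.0, 0.0, 0.0),
                real=(fr, 30.0, 9.4),
                role="center",
                iteration=1,
                run_index=0,
            )
            conv.append(
                simulate.simulate_experiment(point, reactor, noise_rel=0.0).conversion
            )
        assert np.all(np.diff(conv) < 0)

    def test_mass_balance_noise_free(self, reactor, points):
        res = simulate.simulate_experiment(points[4], reactor, noise_rel=0.0)
        assert res.c_substrate + res.c_prod == pytest.approx(res.c0, rel=1e-9)
        assert res.yield_frac == pytest.approx(res.conversion, rel=1e-9)


class TestTrueOptimum:
    def test_oracle_dominates_every_design_point(self, hc3, space):
        reactor = simulate.VirtualReactor(
            geometry=hc3, kinetics=simulate.KineticParams()
        )
        _, sty_best = simulate.true_optimum(reactor, space, grid_n=15)
        for p in doe.generate_ccd(doe.subregion_first(space)):
            res = simulate.simulate_experiment(p, reactor, noise_rel=0.0)
            assert sty_best >= res.sty - 1e-9

    def test_refining_grid_never_decreases_optimum(self, hc3, space):
        reactor = simulate.VirtualReactor(
            geometry=hc3, kinetics=simulate.KineticParams()
        )
        _, coarse = simulate.true_optimum(reactor, space, grid_n=5)
        _, fine = simulate.true_optimum(reactor, space, grid_n=9)  # nested grid
        assert fine >= coarse - 1e-12

    def test_temperature_optimum_on_grid(self, hc3, space):
        reactor = simulate.VirtualReactor(
            geometry=hc3, kinetics=simulate.KineticParams(t_opt=30.0)
        )
        best, _ = simulate.true_optimum(reactor, space, grid_n=21)
        grid = np.linspace(25.0, 35.0, 21)
        nearest = grid[np.argmin(np.abs(grid - 30.0))]
        assert best["temperature"] == pytest.approx(nearest)

    def test_sampled_kinetics_are_reproducible_and_in_range(self):
        a = simulate.sample_kinetics(3)
        b = simulate.sample_kinetics(3)
        assert a == b
        assert 28.0 <= a.t_opt <= 32.0
        assert a.n_tanks >= 1
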