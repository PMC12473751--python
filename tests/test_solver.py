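"""The coupled mass-balance engine: stepping, iteration, trajectories."""

import math
from dataclasses import replace

import numpy as np
import pytest

import blisterstab as bs
from conftest import PSAT_40C, make_tablet, ode_oracle, sealed_equilibrium_rh


class TestSelectTimeStep:
    @pytest.mark.parametrize(
        "sigma, k, expected",
        [
            (1e-2, 4.41, 2.279e-3),
            (1e-2, 5.1e-5, 197.07),
            (1 - math.exp(-1), 2.0, 0.5),  # one relaxation time
        ],
    )
    def test_values(self, sigma, k, expected):
        assert bs.select_time_step(sigma, k) == pytest.approx(expected, rel=1e-3)

    def test_zero_rate_falls_back_to_output_interval(self):
        assert bs.select_time_step(1e-2, 0.0, fallback=3600.0) == 3600.0

    @pytest.mark.parametrize("sigma", [0.0, 1.0, -0.5])
    def test_invalid_sigma(self, sigma):
        with pytest.raises(ValueError):
            bs.select_time_step(sigma, 1.0)


class TestAdvanceStep:
    def test_pure_permeation_half_step(self, geometry):
        # k_perm * dt = ln 2 moves the cavity halfway to ambient: 0.4 -> 0.55
        sc = bs.Scenario(313.0, 0.7, 0.4, geometry, k_perm=1e-4, horizon=1e5,
                         saturation_pressure=PSAT_40C)
        state = bs.advance_step(
            bs.CompartmentState(0.0, bs.vapor_mass(0.4, sc.gas), 0.0, 0.0,
                                0.0, 0.4),
            sc, bs.SolverSettings(), dt=math.log(2) / 1e-4,
        )
        assert state.cavity_rh == pytest.approx(0.55, rel=1e-12)

    def test_global_equilibrium_is_fixed_point(self, geometry, isotherm):
        tab = make_tablet(isotherm)
        sc = bs.Scenario(313.0, 0.5, 0.5, geometry, k_perm=1e-4, tablet=tab,
                         horizon=1e5, saturation_pressure=PSAT_40C)
        m_v = bs.vapor_mass(0.5, sc.gas)
        m_s = bs.sorption_limit(tab, 0.5)
        state0 = bs.CompartmentState(0.0, m_v, m_s, 0.0, 0.0, 0.5)
        for dt in (1.0, 1e4, 1e7):
            state = bs.advance_step(state0, sc, bs.SolverSettings(), dt)
            assert state.vapor_mass == pytest.approx(m_v, rel=1e-12)
            assert state.sorbed_mass == pytest.approx(m_s, rel=1e-12)
            assert state.degraded_water == 0.0

    def test_sealed_step_matches_ode_oracle(self, geometry, isotherm):
        tab = make_tablet(isotherm, initial_load=bs.gab_load(isotherm, 0.2))
        sc = bs.Scenario(313.0, 0.0, 0.7, geometry, k_perm=0.0, tablet=tab,
                         horizon=4e5, saturation_pressure=PSAT_40C)
        settings = bs.SolverSettings(step_criterion=1e-3,
                                     convergence_limit=1e-12,
                                     output_interval=4e5)
        traj = bs.simulate(sc, settings)
        oracle = ode_oracle(sc, traj.time)
        for name in ("sorbed_mass", "degraded_water"):
            np.testing.assert_allclose(
                getattr(traj, name)[1:], oracle[name][1:], rtol=1e-6, atol=1e-18
            )
        np.testing.assert_allclose(
            traj.vapor_mass[1:],
            oracle["cavity_rh"][1:] * sc.gas.vapor_capacity,
            rtol=1e-5,
        )


class TestSimulate:
    def test_empty_blister_matches_analytic_exponential(self, geometry):
        k = 1e-4
        sc = bs.Scenario(313.0, 0.7, 0.4, geometry, k_perm=k, horizon=5e4,
                         saturation_pressure=PSAT_40C)
        traj = bs.simulate(
            sc, bs.SolverSettings(step_criterion=1e-3, output_interval=2.5e3)
        )
        exact = 0.7 - (0.7 - 0.4) * np.exp(-k * traj.time)
        assert np.max(np.abs(traj.cavity_rh - exact)) < 1e-6

    def test_sealed_blister_reaches_equilibrium_oracle(self, geometry, isotherm):
        tab = make_tablet(isotherm, initial_load=bs.gab_load(isotherm, 0.2))
        sc = bs.Scenario(313.0, 0.0, 0.7, geometry, k_perm=0.0, tablet=tab,
                         horizon=6e5, saturation_pressure=PSAT_40C)
        traj = bs.simulate(sc, bs.SolverSettings(output_interval=1e4))
        rh_star = sealed_equilibrium_rh(sc)
        assert traj.cavity_rh[-1] == pytest.approx(rh_star, rel=1e-6)
        # tablet drier than cavity: humidity falls monotonically to
        # equilibrium (up to roundoff on the plateau)
        assert np.all(np.diff(traj.cavity_rh) <= 1e-10)

    def test_mass_conservation_across_suite(self, scenario_suite):
        for name, sc in scenario_suite.items():
            settings = bs.SolverSettings(output_interval=sc.horizon / 40)
            traj = bs.simulate(sc, settings)
            err = traj.mass_balance_error()
            assert np.max(err) <= settings.convergence_limit, name
            traj.validate()

    def test_cavity_rh_bounded_by_driving_humidities(self, scenario_suite):
        for name, sc in scenario_suite.items():
            traj = bs.simulate(
                sc, bs.SolverSettings(output_interval=sc.horizon / 40)
            )
            hi = max(sc.initial_cavity_rh, sc.ambient_rh)
            assert np.all(traj.cavity_rh >= -1e-15), name
            assert np.all(traj.cavity_rh <= hi + 1e-12), name

    def test_full_system_matches_stiff_ode_oracle(self, scenario_suite):
        for name in ("coupled", "sealed", "coupled_fast_sorption"):
            sc = scenario_suite[name]
            traj = bs.simulate(
                sc, bs.SolverSettings(output_interval=sc.horizon / 50)
            )
            oracle = ode_oracle(sc, traj.time)
            assert np.max(np.abs(traj.cavity_rh - oracle["cavity_rh"])) < 1e-3, name

    def test_output_interval_is_pure_recording(self, geometry, isotherm,
                                               fast_degradation):
        sc = bs.Scenario(313.0, 0.7, 0.4, geometry, k_perm=2e-4,
                         tablet=make_tablet(isotherm),
                         degradation=fast_degradation, horizon=2e4,
                         saturation_pressure=PSAT_40C)
        coarse = bs.simulate(sc, bs.SolverSettings(output_interval=4e3))
        fine = bs.simulate(sc, bs.SolverSettings(output_interval=1e3))
        idx = np.searchsorted(fine.time, coarse.time)
        np.testing.assert_allclose(fine.time[idx], coarse.time, rtol=1e-12)
        np.testing.assert_allclose(
            fine.cavity_rh[idx], coarse.cavity_rh, rtol=1e-12
        )
        np.testing.assert_allclose(
            fine.sorbed_mass[idx], coarse.sorbed_mass, rtol=1e-12
        )

    def test_step_refinement_converges(self, geometry, isotherm,
                                       fast_degradation):
        # halving sigma changes the output by less than the previous halving
        sc = bs.Scenario(313.0, 0.7, 0.4, geometry, k_perm=2e-4,
                         tablet=make_tablet(isotherm),
                         degradation=fast_degradation, horizon=2e4,
                         saturation_pressure=PSAT_40C)
        runs = {
            s: bs.simulate(
                sc, bs.SolverSettings(step_criterion=s, output_interval=1e3)
            )
            for s in (4e-2, 2e-2, 1e-2, 5e-3)
        }
        d1 = np.max(np.abs(runs[4e-2].cavity_rh - runs[2e-2].cavity_rh))
        d2 = np.max(np.abs(runs[2e-2].cavity_rh - runs[1e-2].cavity_rh))
        d3 = np.max(np.abs(runs[1e-2].cavity_rh - runs[5e-3].cavity_rh))
        assert d1 > d2 > d3

    def test_unpacked_mode_pins_cavity_to_ambient(self, scenario_suite):
        traj = bs.simulate(
            scenario_suite["unpacked"], bs.SolverSettings(output_interval=1e3)
        )
        np.testing.assert_allclose(traj.cavity_rh, 0.7, atol=1e-12)
        assert traj.drug_content_pct[-1] < 100.0

    def test_barrier_ordering_of_materials(self, geometry, isotherm):
        # lower WVTR (higher barrier) => slower RH rise, slower uptake,
        # higher drug content at all times; low barrier approaches unpacked.
        # A lightly buffered tablet (small dry mass) lets the cavity of the
        # low-barrier variant actually reach the ambient humidity within
        # the test horizon.
        tab = bs.TabletSpec(5e-6, isotherm, sorption_rate=1e-3)
        deg = bs.DegradationSpec(417.5, 10e-6, 3.5e21, 1.71e5, 3.4)
        common = dict(temperature=313.0, ambient_rh=0.7, initial_cavity_rh=0.4,
                      geometry=geometry, tablet=tab, degradation=deg,
                      horizon=4e5, saturation_pressure=PSAT_40C)
        trajs = {}
        for name, kw in {
            "high_barrier": dict(k_perm=7e-6),
            "mid_barrier": dict(k_perm=7e-5),
            "low_barrier": dict(k_perm=7e-4),
            "unpacked": dict(unpacked=True),
        }.items():
            sc = bs.Scenario(**common, **kw)
            trajs[name] = bs.simulate(
                sc, bs.SolverSettings(output_interval=1e4)
            )
        for a, b in [("high_barrier", "mid_barrier"),
                     ("mid_barrier", "low_barrier"),
                     ("low_barrier", "unpacked")]:
            assert np.all(
                trajs[a].cavity_rh[1:] <= trajs[b].cavity_rh[1:] + 1e-12
            )
            assert np.all(
                trajs[a].tablet_load[1:] <= trajs[b].tablet_load[1:] + 1e-12
            )
            assert np.all(
                trajs[a].drug_content_pct[1:]
                >= trajs[b].drug_content_pct[1:] - 1e-12
            )
        # the low-barrier curve lies much closer to the unpacked reference
        # than the high-barrier curve does
        gaps = {
            name: np.max(np.abs(trajs[name].drug_content_pct
                                - trajs["unpacked"].drug_content_pct))
            for name in ("high_barrier", "mid_barrier", "low_barrier")
        }
        assert gaps["low_barrier"] < gaps["mid_barrier"] < gaps["high_barrier"]
        assert gaps["low_barrier"] < 0.25 * gaps["high_barrier"]

    def test_convergence_failure_reports_time(self, geometry, isotherm):
        sc = bs.Scenario(313.0, 0.7, 0.2, geometry, k_perm=1e-4,
                         tablet=make_tablet(isotherm, k_sor=4.41),
                         horizon=1e4, saturation_pressure=PSAT_40C)
        settings = bs.SolverSettings(max_iterations_per_step=1,
                                     convergence_limit=1e-14)
        with pytest.raises(bs.ConvergenceError) as err:
            bs.simulate(sc, settings)
        assert err.value.iterations == 1


class TestDrugContentSeries:
    def test_endpoints(self, degradation):
        cap = bs.degradation_capacity(degradation)
        content = bs.drug_content_series(np.array([0.0, cap / 2, cap]),
                                         degradation)
        np.testing.assert_allclose(content, [100.0, 50.0, 0.0], rtol=1e-12)

    def test_constant_rh_unpacked_matches_closed_form(self, geometry, isotherm,
                                                      fast_degradation):
        # the per-step increments are exact at constant humidity, so the
        # only deviation from the closed form is linear interpolation onto
        # the output grid; a fine step criterion pushes that below 1e-9
        sc = bs.Scenario(313.0, 0.6, 0.6, geometry,
                         tablet=make_tablet(isotherm),
                         degradation=fast_degradation, horizon=2e4,
                         unpacked=True, saturation_pressure=PSAT_40C)
        traj = bs.simulate(
            sc, bs.SolverSettings(step_criterion=2e-5, output_interval=2e3)
        )
        k = bs.degradation_rate(fast_degradation, 313.0, 0.6)
        exact = 100.0 * np.exp(-k * traj.time)
        np.testing.assert_allclose(traj.drug_content_pct, exact, rtol=1e-9)


class TestScenarioValidation:
    def test_requires_permeation_or_unpacked(self, geometry):
        with pytest.raises(ValueError, match="k_perm or wvtr"):
            bs.Scenario(313.0, 0.7, 0.4, geometry, horizon=1e4)

    def test_rh_bounds(self, geometry):
        with pytest.raises(ValueError):
            bs.Scenario(313.0, 1.4, 0.4, geometry, k_perm=1e-4, horizon=1e4)

    def test_tablet_mode_requires_tablet(self, geometry):
        with pytest.raises(ValueError, match="tablet"):
            bs.Scenario(313.0, 0.7, 0.4, geometry, k_perm=1e-4, horizon=1e4,
                        degradation_rh_mode="tablet")

    def test_wvtr_is_converted(self, geometry):
        sc = bs.Scenario(
            313.0, 0.7, 0.4, geometry,
            wvtr=bs.WvtrMeasurement.from_g_per_m2_day(1.0, 0.9, 313.0),
            horizon=1e4, saturation_pressure=PSAT_40C,
        )
        assert sc.permeation_rate() == pytest.approx(2.39e-4, rel=2e-3)
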