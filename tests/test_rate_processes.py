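"""Permeation, sorption and degradation primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import blisterstab as bs
from blisterstab.rate_processes import gab_slope


class TestFirstOrderIncrement:
    def test_half_life(self):
        p = bs.FirstOrderProcess(0.0, 1.0, 1.0)
        assert bs.first_order_increment(p, math.log(2)) == pytest.approx(0.5)

    def test_equilibrium_is_fixed_point(self):
        p = bs.FirstOrderProcess(0.7, 0.7, 3.0)
        for dt in (0.0, 1.0, 1e9):
            assert bs.first_order_increment(p, dt) == 0.7

    def test_step_criterion_consistency(self):
        # one dynamically selected step at sigma = 1e-2 covers 1 % of the gap
        k = 4.41
        dt = bs.select_time_step(1e-2, k)
        assert dt == pytest.approx(2.279e-3, rel=1e-3)
        p = bs.FirstOrderProcess(0.0, 1.0, k)
        assert bs.first_order_increment(p, dt) == pytest.approx(0.01, rel=1e-12)

    def test_zero_rate_freezes_state(self):
        p = bs.FirstOrderProcess(0.3, 1.0, 0.0)
        assert bs.first_order_increment(p, 1e12) == 0.3

    @settings(derandomize=True, max_examples=200)
    @given(
        m0=st.floats(0.0, 2.0),
        m_inf=st.floats(0.0, 2.0),
        k=st.floats(0.0, 1e3),
        dt=st.floats(0.0, 1e3),
        dt2=st.floats(0.0, 1e3),
    )
    def test_never_crosses_limit_and_semigroup(self, m0, m_inf, k, dt, dt2):
        p = bs.FirstOrderProcess(m0, m_inf, k)
        m1 = bs.first_order_increment(p, dt)
        # monotone approach without overshoot
        if m0 <= m_inf:
            assert m0 - 1e-15 <= m1 <= m_inf + 1e-15
        else:
            assert m_inf - 1e-15 <= m1 <= m0 + 1e-15
        # stepping dt then dt2 equals stepping dt + dt2
        m_two = bs.first_order_increment(
            bs.FirstOrderProcess(m1, m_inf, k), dt2
        )
        m_once = bs.first_order_increment(p, dt + dt2)
        assert m_two == pytest.approx(m_once, rel=1e-12, abs=1e-15)


class TestPermeation:
    def test_limit_tracks_ambient_humidity(self, table_gas):
        assert bs.permeation_limit(0.7, table_gas) == pytest.approx(
            1.467e-8, rel=1e-3
        )
        assert bs.permeation_limit(0.0, table_gas) == 0.0
        doubled = bs.GasVolume(2 * table_gas.volume, table_gas.temperature,
                               saturation_pressure=table_gas.saturation_pressure)
        assert bs.permeation_limit(0.7, doubled) == pytest.approx(
            2 * bs.permeation_limit(0.7, table_gas), rel=1e-14
        )

    def test_kperm_from_wvtr_case_study(self, geometry):
        meas = bs.WvtrMeasurement.from_g_per_m2_day(1.0, 0.9, 313.0)
        k = bs.kperm_from_wvtr(meas, geometry, saturation_pressure=7390.0)
        assert k == pytest.approx(2.39e-4, rel=2e-3)

    def test_kperm_linear_in_wvtr(self, geometry):
        m1 = bs.WvtrMeasurement.from_g_per_m2_day(1.0, 0.9, 313.0)
        m2 = bs.WvtrMeasurement.from_g_per_m2_day(2.0, 0.9, 313.0)
        m0 = bs.WvtrMeasurement.from_g_per_m2_day(0.0, 0.9, 313.0)
        assert bs.kperm_from_wvtr(m2, geometry) == pytest.approx(
            2 * bs.kperm_from_wvtr(m1, geometry), rel=1e-12
        )
        assert bs.kperm_from_wvtr(m0, geometry) == 0.0

    def test_zero_donor_humidity_rejected(self):
        with pytest.raises(ValueError):
            bs.WvtrMeasurement.from_g_per_m2_day(1.0, 0.0, 313.0)


class TestGabIsotherm:
    @pytest.mark.parametrize(
        "rh, expected", [(0.7, 0.0675), (0.5, 0.0445), (0.0, 0.0)]
    )
    def test_case_study_loads(self, isotherm, rh, expected):
        assert bs.gab_load(isotherm, rh) == pytest.approx(expected, abs=5e-4)

    def test_monotone_in_rh(self, isotherm):
        loads = [bs.gab_load(isotherm, r) for r in np.linspace(0, 1, 50)]
        assert all(b > a for a, b in zip(loads, loads[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            bs.GabIsotherm(0.03, 8.9, 1.2)  # K >= 1 diverges on [0, 1]
        with pytest.raises(ValueError):
            bs.GabIsotherm(-0.1, 8.9, 0.8)

    def test_activity_inverts_load(self, isotherm):
        assert bs.gab_activity(isotherm, 0.0675) == pytest.approx(0.70, abs=5e-3)
        assert bs.gab_activity(isotherm, 0.0) == 0.0
        rh = 0.35
        back = bs.gab_activity(isotherm, bs.gab_load(isotherm, rh))
        assert back == pytest.approx(rh, rel=1e-10)

    def test_activity_rejects_unattainable_load(self, isotherm):
        with pytest.raises(ValueError, match="attainable"):
            bs.gab_activity(isotherm, 10.0)

    def test_round_trip_random_parameters(self):
        # broad random sweep over parameters and humidities
        rng = np.random.default_rng(42)
        for _ in range(1000):
            iso = bs.GabIsotherm(
                float(rng.uniform(0.005, 0.2)),
                float(rng.uniform(0.5, 200.0)),
                float(rng.uniform(0.05, 0.98)),
            )
            rh = float(rng.uniform(0.0, 1.0))
            load = bs.gab_load(iso, rh)
            assert bs.gab_activity(iso, load) == pytest.approx(
                rh, rel=1e-10, abs=1e-10
            )

    def test_slope_matches_finite_difference(self, isotherm):
        h = 1e-7
        for rh in (0.1, 0.4, 0.8):
            fd = (bs.gab_load(isotherm, rh + h) - bs.gab_load(isotherm, rh - h)) / (2 * h)
            assert gab_slope(isotherm, rh) == pytest.approx(fd, rel=1e-6)

    def test_sorption_limit_scales_with_dry_mass(self, isotherm):
        tab = bs.TabletSpec(3.64e-4, isotherm, sorption_rate=1e-4)
        half = bs.TabletSpec(1.82e-4, isotherm, sorption_rate=1e-4)
        assert bs.sorption_limit(tab, 0.7) == pytest.approx(24.6e-6, rel=2e-3)
        assert bs.sorption_limit(tab, 0.0) == 0.0
        assert bs.sorption_limit(half, 0.7) == pytest.approx(
            bs.sorption_limit(tab, 0.7) / 2, rel=1e-14
        )

    def test_tabulated_sorption_rate_interpolates(self, isotherm):
        tab = bs.TabletSpec(
            3.64e-4, isotherm,
            sorption_rate=[(0.2, 1e-5), (0.8, 7e-5)],
        )
        assert tab.sorption_rate_at(0.2) == 1e-5
        assert tab.sorption_rate_at(0.5) == pytest.approx(4e-5)
        assert tab.sorption_rate_at(0.9) == 7e-5  # clamped at table edge


class TestDegradation:
    def test_capacity_case_study(self, degradation):
        # 10 mg cilazapril, nu = 1: 0.431 mg of water degrades it all
        assert bs.degradation_capacity(degradation) == pytest.approx(
            4.31e-7, rel=1e-3
        )

    def test_capacity_linear_in_stoichiometry(self, degradation):
        from dataclasses import replace

        doubled = replace(degradation, stoichiometric_factor=2.0)
        empty = replace(degradation, drug_mass=0.0)
        assert bs.degradation_capacity(doubled) == pytest.approx(
            2 * bs.degradation_capacity(degradation), rel=1e-14
        )
        assert bs.degradation_capacity(empty) == 0.0

    def test_degraded_mass_inverts_capacity(self, degradation):
        cap = bs.degradation_capacity(degradation)
        assert bs.degraded_drug_mass(degradation, cap) == pytest.approx(
            10e-6, rel=1e-12
        )
        assert bs.degraded_drug_mass(degradation, 0.0) == 0.0
        assert bs.degraded_drug_mass(degradation, cap / 2) == pytest.approx(
            5e-6, rel=1e-12
        )

    def test_overconsumption_rejected(self, degradation):
        cap = bs.degradation_capacity(degradation)
        with pytest.raises(ValueError, match="capacity"):
            bs.degraded_drug_mass(degradation, 1.5 * cap)

    def test_rate_humidity_independent_when_b_zero(self, degradation):
        from dataclasses import replace

        no_b = replace(degradation, humidity_factor=0.0)
        k_dry = bs.degradation_rate(no_b, 313.0, 0.0)
        assert bs.degradation_rate(no_b, 313.0, 0.7) == k_dry
        expected = 5.43e18 * math.exp(-1.71e5 / (8.314 * 313.0))
        assert k_dry == pytest.approx(expected, rel=1e-12)

    def test_humidity_acceleration_factor(self, degradation):
        ratio = bs.degradation_rate(degradation, 313.0, 0.7) / bs.degradation_rate(
            degradation, 313.0, 0.0
        )
        assert ratio == pytest.approx(math.exp(3.4 * 0.7), rel=1e-12)
        assert ratio == pytest.approx(10.8, abs=0.05)

    def test_case_study_rate_magnitude(self, degradation):
        # shelf-life-scale kinetics under the negative-exponent convention
        k = bs.degradation_rate(degradation, 313.0, 0.7)
        assert k == pytest.approx(1.7e-9, rel=0.01)

    def test_monotone_in_rh_and_temperature(self, degradation):
        ks = [bs.degradation_rate(degradation, 313.0, r)
              for r in np.linspace(0, 1, 11)]
        assert all(b > a for a, b in zip(ks, ks[1:]))
        kts = [bs.degradation_rate(degradation, t, 0.5)
               for t in (293.0, 313.0, 333.0)]
        assert kts[0] < kts[1] < kts[2]

    def test_positive_sign_convention_flips_temperature_trend(self, degradation):
        from dataclasses import replace

        pos = replace(degradation, arrhenius_sign=1)
        assert bs.degradation_rate(pos, 333.0, 0.5) < bs.degradation_rate(
            pos, 293.0, 0.5
        )
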