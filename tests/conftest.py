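"""Shared fixtures: published case-study parameters and independent oracles.

The numerical oracles here (stiff ODE integration, scalar root finding,
closed-form exponentials) are deliberately built on different machinery
than the solver they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

import blisterstab as bs

#: Saturation pressure of water at 40 degC as tabulated in the case study (Pa).
PSAT_40C = 7390.0


@pytest.fixture(scope="session")
def table_gas() -> bs.GasVolume:
    """Case-study cavity headspace: 0.41 mL at 313 K, pinned p_sat."""
    return bs.GasVolume(0.41e-6, 313.0, saturation_pressure=PSAT_40C)


@pytest.fixture(scope="session")
def geometry() -> bs.BlisterGeometry:
    return bs.BlisterGeometry(0.41e-6, 3.9e-4)


@pytest.fixture(scope="session")
def isotherm() -> bs.GabIsotherm:
    """Case-study placebo-tablet GAB isotherm."""
    return bs.GabIsotherm(0.0296, 8.93, 0.847)


@pytest.fixture(scope="session")
def degradation() -> bs.DegradationSpec:
    """Cilazapril degradation with the shelf-life-scale pre-exponential."""
    return bs.DegradationSpec(
        drug_molar_mass=417.5,
        drug_mass=10e-6,
        pre_exponential=5.43e18,
        activation_energy=1.71e5,
        humidity_factor=3.4,
    )


@pytest.fixture(scope="session")
def fast_degradation() -> bs.DegradationSpec:
    """A synthetic fast-degrading drug for short-horizon solver tests.

    Same humidity sensitivity and activation energy as the case-study drug
    but a pre-exponential chosen so that degradation progresses visibly
    within hours instead of years.
    """
    return bs.DegradationSpec(
        drug_molar_mass=417.5,
        drug_mass=10e-6,
        pre_exponential=3.4e23,
        activation_energy=1.71e5,
        humidity_factor=3.4,
    )


def make_tablet(isotherm, k_sor=5.1e-5, initial_load=None):
    if initial_load is None:
        initial_load = bs.rate_processes.EQUILIBRIUM_SENTINEL
    return bs.TabletSpec(3.64e-4, isotherm, sorption_rate=k_sor,
                         initial_load=initial_load)


def ode_oracle(scenario: bs.Scenario, t_eval: np.ndarray) -> dict[str, np.ndarray]:
    """Stiff adaptive integration of the three coupled rate equations.

    Independent of the package's stepping engine: the coupled ODE system
    is handed to a BDF integrator at tight tolerances, with the state
    scaled to micrograms for conditioning.  Returns the cavity RH, sorbed
    mass and consumed-water series at `t_eval`.
    """
    gas = scenario.gas
    cap = gas.vapor_capacity
    k_perm = scenario.permeation_rate()
    m_env = bs.vapor_mass(scenario.ambient_rh, gas)
    tab, deg = scenario.tablet, scenario.degradation
    cap_deg = bs.degradation_capacity(deg) if deg is not None else 0.0

    def rhs(_t, y):
        mv, ms, md = y * 1e-9
        rh = min(max(mv / cap, 0.0), 1.0)
        dms = (
            tab.sorption_rate_at(rh)
            * (bs.gab_load(tab.isotherm, rh) * tab.dry_mass - ms)
            if tab is not None
            else 0.0
        )
        dmd = (
            bs.degradation_rate(deg, scenario.temperature, rh) * (cap_deg - md)
            if deg is not None
            else 0.0
        )
        return np.array([k_perm * (m_env - mv) - dms - dmd, dms, dmd]) * 1e9

    if tab is None:
        m_s0 = 0.0
    elif tab.initial_load == bs.rate_processes.EQUILIBRIUM_SENTINEL:
        m_s0 = bs.gab_load(tab.isotherm, scenario.initial_cavity_rh) * tab.dry_mass
    else:
        m_s0 = tab.initial_load * tab.dry_mass
    y0 = np.array(
        [bs.vapor_mass(scenario.initial_cavity_rh, gas), m_s0, 0.0]
    ) * 1e9
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), y0, method="BDF",
                    t_eval=t_eval, rtol=1e-10, atol=1e-12)
    assert sol.success
    return {
        "cavity_rh": sol.y[0] * 1e-9 / cap,
        "sorbed_mass": sol.y[1] * 1e-9,
        "degraded_water": sol.y[2] * 1e-9,
    }


def sealed_equilibrium_rh(scenario: bs.Scenario) -> float:
    """Root-finding oracle for the common water activity of a sealed system."""
    gas = scenario.gas
    tab = scenario.tablet
    if tab.initial_load == bs.rate_processes.EQUILIBRIUM_SENTINEL:
        load0 = bs.gab_load(tab.isotherm, scenario.initial_cavity_rh)
    else:
        load0 = tab.initial_load
    total = bs.vapor_mass(scenario.initial_cavity_rh, gas) + load0 * tab.dry_mass

    def balance(rh):
        return bs.vapor_mass(rh, gas) + bs.gab_load(tab.isotherm, rh) * tab.dry_mass - total

    return brentq(balance, 0.0, 1.0, xtol=1e-16, rtol=8.9e-16)


@pytest.fixture(scope="session")
def scenario_suite(geometry, isotherm, degradation, fast_degradation):
    """Six short-horizon scenarios spanning the model's regimes."""
    tab = make_tablet(isotherm)
    tab_dry = make_tablet(isotherm, initial_load=bs.gab_load(isotherm, 0.2))
    tab_fast = make_tablet(isotherm, k_sor=0.1)
    common = dict(temperature=313.0, geometry=geometry,
                  saturation_pressure=PSAT_40C)
    return {
        "empty": bs.Scenario(ambient_rh=0.7, initial_cavity_rh=0.4,
                             k_perm=1e-4, horizon=5e4, **common),
        "sealed": bs.Scenario(ambient_rh=0.0, initial_cavity_rh=0.7,
                              k_perm=0.0, tablet=tab_dry, horizon=4e5,
                              **common),
        "coupled": bs.Scenario(ambient_rh=0.7, initial_cavity_rh=0.4,
                               k_perm=1e-5, tablet=tab,
                               degradation=degradation, horizon=2e6, **common),
        "coupled_fast_sorption": bs.Scenario(
            ambient_rh=0.7, initial_cavity_rh=0.4, k_perm=2e-5,
            tablet=tab_fast, degradation=degradation, horizon=2e6, **common),
        "fast_degradation": bs.Scenario(
            ambient_rh=0.7, initial_cavity_rh=0.4, k_perm=2e-4, tablet=tab,
            degradation=fast_degradation, horizon=2e4, **common),
        "unpacked": bs.Scenario(ambient_rh=0.7, initial_cavity_rh=0.7,
                                tablet=tab, degradation=fast_degradation,
                                horizon=2e4, unpacked=True, **common),
    }
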