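"""The three first-order water rate processes of a blistered tablet.

Water entering a blister cavity is partitioned between three compartments,
each of which relaxes toward an upper limit with first-order kinetics
``dm/dt = k (m_inf - m)``:

* **permeation** — vapor enters through the blister foil; the limit is the
  vapor mass the cavity would hold in equilibrium with the ambient humidity,
  and the rate constant follows from the foil's water vapor transmission
  rate (WVTR);
* **sorption** — the tablet takes up water toward the equilibrium moisture
  load given by its GAB sorption isotherm at the cavity humidity;
* **degradation** — hydrolysis consumes water stoichiometrically with drug
  loss; the rate constant follows a humidity-corrected Arrhenius law
  ``k = k0 * exp(-Ea/(R T)) * exp(B * rh)``.

Everything here is a pure function of state; the coupling between the
processes lives in :mod:`blisterstab.solver`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .moist_air import GasVolume, MOLAR_MASS_WATER, R_GAS, vapor_mass

__all__ = [
    "FirstOrderProcess",
    "WvtrMeasurement",
    "BlisterGeometry",
    "GabIsotherm",
    "TabletSpec",
    "DegradationSpec",
    "first_order_increment",
    "permeation_limit",
    "kperm_from_wvtr",
    "gab_load",
    "gab_activity",
    "sorption_limit",
    "degradation_capacity",
    "degraded_drug_mass",
    "degradation_rate",
    "EQUILIBRIUM_SENTINEL",
]

#: Sentinel for "initial tablet moisture = GAB equilibrium at the initial
#: cavity humidity".
EQUILIBRIUM_SENTINEL = "equilibrium-at-initial-rh"

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class FirstOrderProcess:
    """State of one first-order compartment: current mass, limit, rate."""

    current_mass: float  # kg
    limit_mass: float  # kg
    rate_constant: float  # 1/s

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError(f"rate_constant must be >= 0, got {self.rate_constant}")
        if self.current_mass < 0:
            raise ValueError(f"current_mass must be >= 0, got {self.current_mass}")


@dataclass(frozen=True)
class WvtrMeasurement:
    """A steady-state water vapor transmission measurement of a foil/cavity.

    `wvtr` is in kg m^-2 s^-1 (SI); use :meth:`from_g_per_m2_day` for the
    customary unit.  `donor_rh` is the relative humidity of the wet (donor)
    cell, `test_temperature` the measurement temperature in K.
    """

    wvtr: float
    donor_rh: float
    test_temperature: float

    def __post_init__(self) -> None:
        if self.wvtr < 0:
            raise ValueError(f"wvtr must be >= 0, got {self.wvtr}")
        if not 0 < self.donor_rh <= 1:
            raise ValueError(f"donor_rh must lie in (0, 1], got {self.donor_rh}")

    @classmethod
    def from_g_per_m2_day(
        cls, wvtr: float, donor_rh: float, test_temperature: float
    ) -> "WvtrMeasurement":
        return cls(wvtr * 1e-3 / SECONDS_PER_DAY, donor_rh, test_temperature)


@dataclass(frozen=True)
class BlisterGeometry:
    """Cavity gas volume (m^3) and permeable surface area (m^2)."""

    cavity_volume: float
    cavity_area: float

    def __post_init__(self) -> None:
        if not self.cavity_volume > 0:
            raise ValueError(f"cavity_volume must be > 0, got {self.cavity_volume}")
        if not self.cavity_area > 0:
            raise ValueError(f"cavity_area must be > 0, got {self.cavity_area}")


@dataclass(frozen=True)
class GabIsotherm:
    """Guggenheim–Anderson–de Boer sorption isotherm.

    ``X(rh) = wm * C * K * rh / ((1 - K rh) (1 - K rh + C K rh))``

    with the moisture load X in g water per g dry solid.  ``0 < k_gab < 1``
    keeps the expression finite on the whole humidity interval [0, 1].
    """

    monolayer_load: float  # wm, g/g
    c_gab: float
    k_gab: float

    def __post_init__(self) -> None:
        if not self.monolayer_load > 0:
            raise ValueError(f"monolayer_load must be > 0, got {self.monolayer_load}")
        if not self.c_gab > 0:
            raise ValueError(f"c_gab must be > 0, got {self.c_gab}")
        if not 0 < self.k_gab < 1:
            raise ValueError(f"k_gab must lie in (0, 1), got {self.k_gab}")


@dataclass(frozen=True)
class TabletSpec:
    """Tablet as a sorbing solid: dry mass, isotherm, sorption kinetics.

    `sorption_rate` is either a constant (1/s) or a sequence of
    ``(rh, k)`` pairs interpolated linearly in rh (the tabulated form for
    humidity-dependent sorption kinetics).  `initial_load` is the moisture
    load at t = 0 in g/g, or the sentinel
    :data:`EQUILIBRIUM_SENTINEL` meaning "in equilibrium with the initial
    cavity humidity".
    """

    dry_mass: float  # kg
    isotherm: GabIsotherm
    sorption_rate: float | Sequence[tuple[float, float]] = 0.0
    initial_load: float | str = EQUILIBRIUM_SENTINEL

    def __post_init__(self) -> None:
        if not self.dry_mass > 0:
            raise ValueError(f"dry_mass must be > 0, got {self.dry_mass}")
        if isinstance(self.sorption_rate, (int, float)):
            if self.sorption_rate < 0:
                raise ValueError(
                    f"sorption_rate must be >= 0, got {self.sorption_rate}"
                )
        else:
            table = tuple((float(r), float(k)) for r, k in self.sorption_rate)
            if len(table) < 2:
                raise ValueError("tabulated sorption_rate needs >= 2 (rh, k) pairs")
            rhs = [r for r, _ in table]
            if sorted(rhs) != rhs or len(set(rhs)) != len(rhs):
                raise ValueError("tabulated sorption_rate must be sorted in rh")
            if any(k < 0 for _, k in table):
                raise ValueError("tabulated sorption_rate values must be >= 0")
            object.__setattr__(self, "sorption_rate", table)
        if isinstance(self.initial_load, str):
            if self.initial_load != EQUILIBRIUM_SENTINEL:
                raise ValueError(
                    f"initial_load must be a number or {EQUILIBRIUM_SENTINEL!r}"
                )
        elif self.initial_load < 0:
            raise ValueError(f"initial_load must be >= 0, got {self.initial_load}")

    def sorption_rate_at(self, rh: float) -> float:
        """Sorption rate constant (1/s) at cavity humidity `rh`."""
        if isinstance(self.sorption_rate, (int, float)):
            return float(self.sorption_rate)
        rhs = np.array([r for r, _ in self.sorption_rate])
        ks = np.array([k for _, k in self.sorption_rate])
        return float(np.interp(rh, rhs, ks))


@dataclass(frozen=True)
class DegradationSpec:
    """Hydrolytic degradation of the drug load of one tablet.

    ``drug_molar_mass`` in g/mol, ``drug_mass`` (the full drug load) in kg.
    ``stoichiometric_factor`` is the moles of water consumed per mole of
    drug degraded (default 1).  The rate constant follows the
    humidity-corrected Arrhenius law with pre-exponential ``pre_exponential``
    (1/s), activation energy ``activation_energy`` (J/mol) and humidity
    sensitivity ``humidity_factor`` (dimensionless).  ``arrhenius_sign``
    selects the sign convention of the activation-energy exponent; the
    default ``-1`` is the standard Arrhenius form.
    """

    drug_molar_mass: float
    drug_mass: float
    pre_exponential: float
    activation_energy: float
    humidity_factor: float
    stoichiometric_factor: float = 1.0
    arrhenius_sign: int = -1

    def __post_init__(self) -> None:
        if not self.drug_molar_mass > 0:
            raise ValueError(
                f"drug_molar_mass must be > 0, got {self.drug_molar_mass}"
            )
        for name in ("drug_mass", "pre_exponential", "activation_energy",
                     "stoichiometric_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.arrhenius_sign not in (-1, 1):
            raise ValueError(f"arrhenius_sign must be -1 or +1, got {self.arrhenius_sign}")


# ---------------------------------------------------------------------------
# generic first-order step


def first_order_increment(process: FirstOrderProcess, dt: float) -> float:
    """Water mass after stepping a first-order process by `dt` seconds.

    Exact integral of ``dm/dt = k (m_inf - m)`` over the step:

        m(t + dt) = m_inf - (m_inf - m(t)) * exp(-k dt)

    The result approaches the limit monotonically and never overshoots; it
    is exact for constant `k` and `m_inf`, hence unconditionally stable for
    any step size.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if process.rate_constant * dt == 0.0:
        return process.current_mass
    m_inf = process.limit_mass
    return m_inf - (m_inf - process.current_mass) * math.exp(
        -process.rate_constant * dt
    )


# ---------------------------------------------------------------------------
# permeation


def permeation_limit(ambient_rh: float, gas: GasVolume) -> float:
    """Equilibrium vapor mass (kg) of the cavity at the ambient humidity."""
    return vapor_mass(ambient_rh, gas)


def kperm_from_wvtr(
    meas: WvtrMeasurement,
    geom: BlisterGeometry,
    saturation_pressure: float | None = None,
) -> float:
    """Permeation rate constant (1/s) from a steady-state WVTR measurement.

    In steady state the measured flux through the cavity area equals the
    first-order permeation flow driven by the donor-cell humidity, the
    acceptor acting as a sink.  Solving for the rate constant:

        k_perm = WVTR * A * R * T / (rh_wet * M_w * V * p_sat(T))

    `saturation_pressure` (Pa) overrides the built-in correlation at the
    test temperature when a tabulated value is prescribed.
    """
    gas = GasVolume(geom.cavity_volume, meas.test_temperature,
                    saturation_pressure=saturation_pressure)
    donor_mass = vapor_mass(meas.donor_rh, gas)
    if donor_mass <= 0:
        raise ZeroDivisionError(
            "donor-cell humidity is zero: the WVTR measurement carries no "
            "driving force and cannot be converted to a rate constant"
        )
    return meas.wvtr * geom.cavity_area / donor_mass


# ---------------------------------------------------------------------------
# sorption


def gab_load(iso: GabIsotherm, rh: float) -> float:
    """Equilibrium moisture load (g water / g dry solid) at humidity `rh`."""
    if not 0.0 <= rh <= 1.0:
        raise ValueError(f"relative humidity must lie in [0, 1], got {rh}")
    u = iso.k_gab * rh
    if u >= 1.0:
        raise ValueError(
            f"k_gab * rh = {u} >= 1: GAB expression diverges; "
            "isotherm parameters invalid at this humidity"
        )
    return iso.monolayer_load * iso.c_gab * u / ((1.0 - u) * (1.0 - u + iso.c_gab * u))


def gab_activity(iso: GabIsotherm, load: float) -> float:
    """Water activity (fraction) at which the isotherm gives `load` g/g.

    Numerical inverse of :func:`gab_load` by bracketed root finding; the
    round trip ``gab_load(iso, gab_activity(iso, X)) == X`` holds to
    better than 1e-10 relative.
    """
    if load < 0:
        raise ValueError(f"load must be >= 0, got {load}")
    if load == 0.0:
        return 0.0
    max_load = gab_load(iso, 1.0)
    if load > max_load:
        raise ValueError(
            f"load {load} g/g exceeds the isotherm's maximum attainable "
            f"load {max_load:.6g} g/g at rh = 1"
        )
    if load == max_load:
        return 1.0
    return float(brentq(lambda r: gab_load(iso, r) - load, 0.0, 1.0,
                        xtol=1e-15, rtol=8.9e-16))


def gab_slope(iso: GabIsotherm, rh: float) -> float:
    """d(load)/d(rh) of the GAB isotherm, g/g per unit relative humidity."""
    u = iso.k_gab * rh
    c = iso.c_gab
    d = (1.0 - u) * (1.0 - u + c * u)
    dd_du = -(1.0 - u + c * u) + (1.0 - u) * (c - 1.0)
    dx_du = iso.monolayer_load * c * (d - u * dd_du) / (d * d)
    return dx_du * iso.k_gab


def sorption_limit(tab: TabletSpec, cavity_rh: float) -> float:
    """Equilibrium sorbed water mass (kg) of the tablet at `cavity_rh`."""
    return gab_load(tab.isotherm, cavity_rh) * tab.dry_mass


# ---------------------------------------------------------------------------
# degradation


def degradation_capacity(deg: DegradationSpec) -> float:
    """Water mass (kg) needed to hydrolyse the entire drug load.

    ``m_w,inf = nu * M_w / M_d * m_drug`` — constant over a simulation.
    """
    return (
        deg.stoichiometric_factor
        * (MOLAR_MASS_WATER * 1e3)
        / deg.drug_molar_mass
        * deg.drug_mass
    )


def degraded_drug_mass(deg: DegradationSpec, water_consumed: float,
                       rtol: float = 1e-9) -> float:
    """Drug mass (kg) degraded after consuming `water_consumed` kg of water.

    Inverse of the stoichiometric relation; equals the full drug load when
    the consumed water equals :func:`degradation_capacity`.
    """
    if water_consumed < 0:
        raise ValueError(f"water_consumed must be >= 0, got {water_consumed}")
    cap = degradation_capacity(deg)
    if water_consumed > cap * (1.0 + rtol):
        raise ValueError(
            f"water_consumed {water_consumed} kg exceeds the degradation "
            f"capacity {cap} kg"
        )
    return deg.drug_mass * min(water_consumed / cap, 1.0) if cap > 0 else 0.0


def degradation_rate(deg: DegradationSpec, T: float, rh: float) -> float:
    """Humidity-corrected Arrhenius degradation rate constant (1/s).

    ``k = k0 * exp(sign * Ea / (R T)) * exp(B * rh)`` with ``sign`` the
    spec's convention flag (default negative, the standard Arrhenius form).
    """
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    if not 0.0 <= rh <= 1.0:
        raise ValueError(f"relative humidity must lie in [0, 1], got {rh}")
    return (
        deg.pre_exponential
        * math.exp(deg.arrhenius_sign * deg.activation_energy / (R_GAS * T))
        * math.exp(deg.humidity_factor * rh)
    )
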