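"""Psychrometrics of the blister-cavity headspace.

The headspace of a sealed blister cavity is a small, isothermal gas volume.
Water vapor in it is treated as an ideal gas, so the water mass held in the
cavity at a given relative humidity follows directly from the ideal gas law:

    m_w = rh * M_w * V * p_sat(T) / (R * T)

This linear relation between relative humidity and vapor mass is the pivot of
the whole mass-balance model: every rate process reads the cavity humidity
from the vapor mass and writes back to it.

Saturation vapor pressure is supplied either by a built-in correlation
(Arden Buck by default, Magnus as an alternative) or as an explicit value on
:class:`GasVolume` when a scenario pins it to a tabulated steam-table number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "R_GAS",
    "MOLAR_MASS_WATER",
    "GasVolume",
    "SupersaturationWarning",
    "saturation_vapor_pressure",
    "vapor_mass",
    "relative_humidity",
]

R_GAS = 8.314
"""Ideal gas constant, J mol^-1 K^-1."""

MOLAR_MASS_WATER = 0.018
"""Molar mass of water, kg mol^-1."""

#: Validity interval of the built-in saturation-pressure correlations (K).
T_VALID = (273.0, 373.15)


class SupersaturationWarning(UserWarning):
    """Computed cavity relative humidity exceeds 1 (condensation regime)."""


def _psat_buck(temperature: float) -> float:
    # Arden Buck correlation for liquid water (Pa); t in deg C.
    t = temperature - 273.15
    return 611.21 * math.exp((18.678 - t / 234.5) * (t / (257.14 + t)))


def _psat_magnus(temperature: float) -> float:
    # Magnus form (WMO coefficients), Pa.
    t = temperature - 273.15
    return 610.94 * math.exp(17.625 * t / (t + 243.04))


_CORRELATIONS = {"buck": _psat_buck, "magnus": _psat_magnus}


def saturation_vapor_pressure(temperature: float, correlation: str = "buck") -> float:
    """Saturation vapor pressure of water over the liquid, in Pa.

    Parameters
    ----------
    temperature
        Absolute temperature in K. Must lie in the correlation's validity
        interval [273.0, 373.15] K.
    correlation
        Name of the closed-form correlation: ``"buck"`` (default) or
        ``"magnus"``.

    Returns
    -------
    float
        Saturation pressure in Pa; strictly positive and strictly increasing
        with temperature over the valid interval.
    """
    lo, hi = T_VALID
    if not lo <= temperature <= hi:
        raise ValueError(
            f"temperature {temperature} K outside the validity interval "
            f"[{lo}, {hi}] K of the saturation-pressure correlation"
        )
    try:
        fn = _CORRELATIONS[correlation]
    except KeyError:
        raise ValueError(
            f"unknown saturation-pressure correlation {correlation!r}; "
            f"available: {sorted(_CORRELATIONS)}"
        ) from None
    return fn(temperature)


@dataclass(frozen=True)
class GasVolume:
    """A fixed, isothermal gas volume (the blister-cavity headspace).

    Parameters
    ----------
    volume
        Gas volume in m^3.
    temperature
        Absolute temperature in K.
    saturation_pressure
        Optional explicit saturation vapor pressure in Pa.  When given it
        overrides the built-in correlation — used when a scenario pins the
        saturation pressure to a tabulated value.
    correlation
        Correlation used when ``saturation_pressure`` is None.
    """

    volume: float
    temperature: float
    saturation_pressure: float | None = None
    correlation: str = "buck"

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.saturation_pressure is not None and not self.saturation_pressure > 0:
            raise ValueError(
                f"saturation_pressure must be > 0, got {self.saturation_pressure}"
            )

    @property
    def p_sat(self) -> float:
        """Saturation pressure in effect for this volume, Pa."""
        if self.saturation_pressure is not None:
            return self.saturation_pressure
        return saturation_vapor_pressure(self.temperature, self.correlation)

    @property
    def vapor_capacity(self) -> float:
        """Water mass (kg) the volume holds at 100 % relative humidity."""
        return (
            MOLAR_MASS_WATER
            * self.volume
            * self.p_sat
            / (R_GAS * self.temperature)
        )


def vapor_mass(rh: float, gas: GasVolume) -> float:
    """Water mass (kg) present in `gas` at relative humidity `rh`.

    `rh` is a fraction in [0, 1]; the result is linear in both `rh` and the
    gas volume.
    """
    if not 0.0 <= rh <= 1.0:
        raise ValueError(f"relative humidity must lie in [0, 1], got {rh}")
    return rh * gas.vapor_capacity


def relative_humidity(mass: float, gas: GasVolume) -> float:
    """Relative humidity (fraction) of `gas` holding `mass` kg of water.

    Exact inverse of :func:`vapor_mass`.  A result above 1 is physically a
    condensation regime; it is returned as-is with a
    :class:`SupersaturationWarning`.
    """
    if mass < 0:
        raise ValueError(f"water mass must be >= 0, got {mass}")
    rh = mass / gas.vapor_capacity
    if rh > 1.0:
        warnings.warn(
            f"computed relative humidity {rh:.4f} exceeds saturation",
            SupersaturationWarning,
            stacklevel=2,
        )
    return rh
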