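"""Scenario configuration files.

A scenario is described in YAML with five sections — ``environment``,
``blister``, ``tablet``, ``drug``, ``solver`` — mapping one-to-one onto
:class:`~blisterstab.solver.Scenario` and
:class:`~blisterstab.solver.SolverSettings`.  Every dimensional entry
carries an explicit unit string (``"313 K"``, ``{value: 0.41, unit: mL}``);
bare numbers are accepted only for dimensionless quantities.  Unknown keys
are rejected with their full key path, and all schema violations in a file
are reported together.

Two example configurations ship with the package (see
:func:`example_config_path`): ``case_study`` uses the published cilazapril
parameter set verbatim — including a pre-exponential factor whose printed
magnitude yields degradation half-lives of astronomical length, which
triggers a load-time plausibility warning — and ``case_study_reinterpreted``
uses the positive-exponent reading of that factor, which yields
shelf-life-scale rates.
"""

from __future__ import annotations

import math
import warnings
from importlib import resources
from pathlib import Path

import yaml

from . import rate_processes as rp
from .solver import Scenario, SolverSettings

__all__ = [
    "SchemaError",
    "ParameterPlausibilityWarning",
    "load_scenario",
    "save_scenario",
    "scenario_to_dict",
    "settings_to_dict",
    "example_config_path",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """One or more configuration entries are invalid; lists every problem."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid scenario configuration:\n  - " + "\n  - ".join(self.problems)
        )


class ParameterPlausibilityWarning(UserWarning):
    """A loaded parameter combination yields physically implausible rates."""


# ---------------------------------------------------------------------------
# unit handling — a small declared-units table; no silent defaults

_DAY = 86400.0
_UNIT_TABLES: dict[str, dict[str, float]] = {
    "temperature": {"K": 1.0},  # degC handled separately (offset)
    "volume": {"m^3": 1.0, "m3": 1.0, "L": 1e-3, "mL": 1e-6, "ml": 1e-6,
               "cm^3": 1e-6, "uL": 1e-9},
    "area": {"m^2": 1.0, "m2": 1.0, "cm^2": 1e-4, "cm2": 1e-4,
             "mm^2": 1e-6, "mm2": 1e-6},
    "mass": {"kg": 1.0, "g": 1e-3, "mg": 1e-6, "ug": 1e-9},
    "time": {"s": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0,
             "day": _DAY, "d": _DAY, "year": 365.0 * _DAY, "yr": 365.0 * _DAY},
    "rate": {"1/s": 1.0, "s^-1": 1.0, "1/min": 1 / 60.0, "1/h": 1 / 3600.0,
             "h^-1": 1 / 3600.0, "1/day": 1 / _DAY, "day^-1": 1 / _DAY},
    "pressure": {"Pa": 1.0, "kPa": 1e3, "hPa": 1e2, "bar": 1e5, "mbar": 1e2},
    "wvtr": {"kg/m^2/s": 1.0, "g/m^2/day": 1e-3 / _DAY},
    "molar_mass": {"g/mol": 1.0, "kg/mol": 1e3},
    "energy_molar": {"J/mol": 1.0, "kJ/mol": 1e3},
    "load": {"g/g": 1.0, "kg/kg": 1.0, "mg/g": 1e-3},
    "fraction": {"-": 1.0, "": 1.0, "frac": 1.0, "%": 1e-2},
    "dimensionless": {"-": 1.0, "": 1.0},
}


def _parse_quantity(raw, kind: str, path: str, problems: list[str]):
    """Parse a value-with-unit entry into SI; append problems on failure."""
    value, unit = None, None
    if isinstance(raw, str):
        parts = raw.split(None, 1)
        try:
            value = float(parts[0])
            unit = parts[1].strip() if len(parts) > 1 else ""
        except (ValueError, IndexError):
            problems.append(f"{path}: cannot parse quantity {raw!r}")
            return None
    elif isinstance(raw, dict):
        extra = set(raw) - {"value", "unit"}
        if extra or "value" not in raw:
            problems.append(
                f"{path}: quantity mapping must have keys 'value' and 'unit'"
            )
            return None
        value = raw["value"]
        unit = raw.get("unit", "")
    elif isinstance(raw, (list, tuple)) and len(raw) == 2:
        value, unit = raw
    elif isinstance(raw, (int, float)):
        value, unit = float(raw), ""
    else:
        problems.append(f"{path}: cannot parse quantity {raw!r}")
        return None

    try:
        value = float(value)
    except (TypeError, ValueError):
        problems.append(f"{path}: value {value!r} is not numeric")
        return None
    unit = str(unit).strip()

    if kind == "temperature":
        if unit == "K":
            return value
        if unit in ("degC", "C", "°C"):
            return value + 273.15
        problems.append(
            f"{path}: unit {unit!r} is not a temperature unit (K, degC)"
        )
        return None
    table = _UNIT_TABLES[kind]
    if unit == "" and kind not in ("fraction", "dimensionless"):
        problems.append(f"{path}: missing unit (expected one of {sorted(table)})")
        return None
    if unit not in table:
        problems.append(
            f"{path}: unit {unit!r} not valid for {kind} "
            f"(expected one of {sorted(table)})"
        )
        return None
    return value * table[unit]


def _check_keys(section: dict, allowed: set[str], path: str,
                problems: list[str]) -> None:
    for key in section:
        if key not in allowed:
            problems.append(f"{path}.{key}: unknown key")


# ---------------------------------------------------------------------------
# loading


def load_scenario(path) -> tuple[Scenario, SolverSettings]:
    """Load and validate a YAML scenario file.

    Returns fully unit-converted ``(Scenario, SolverSettings)``.  All schema
    violations are collected and raised together as :class:`SchemaError`.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(["file does not contain a mapping"])
    problems: list[str] = []

    if doc.get("schema_version") != SCHEMA_VERSION:
        problems.append(
            f"schema_version: expected {SCHEMA_VERSION}, "
            f"got {doc.get('schema_version')!r}"
        )
    _check_keys(doc, {"schema_version", "environment", "blister", "tablet",
                      "drug", "solver"}, "<root>", problems)

    env = doc.get("environment")
    if not isinstance(env, dict):
        problems.append("environment: section missing or not a mapping")
        env = {}
    _check_keys(env, {"temperature", "ambient_rh", "initial_cavity_rh",
                      "saturation_pressure", "horizon"}, "environment", problems)
    temperature = _parse_quantity(env.get("temperature", "nan K"),
                                  "temperature", "environment.temperature",
                                  problems)
    ambient_rh = _parse_quantity(env.get("ambient_rh", 0.0), "fraction",
                                 "environment.ambient_rh", problems)
    initial_rh = _parse_quantity(env.get("initial_cavity_rh", 0.0), "fraction",
                                 "environment.initial_cavity_rh", problems)
    horizon = _parse_quantity(env.get("horizon", "1 day"), "time",
                              "environment.horizon", problems)
    p_sat = None
    if "saturation_pressure" in env:
        p_sat = _parse_quantity(env["saturation_pressure"], "pressure",
                                "environment.saturation_pressure", problems)

    blis = doc.get("blister")
    if not isinstance(blis, dict):
        problems.append("blister: section missing or not a mapping")
        blis = {}
    _check_keys(blis, {"cavity_volume", "cavity_area", "k_perm", "wvtr",
                       "unpacked"}, "blister", problems)
    volume = _parse_quantity(blis.get("cavity_volume", "nan m^3"), "volume",
                             "blister.cavity_volume", problems)
    area = _parse_quantity(blis.get("cavity_area", "nan m^2"), "area",
                           "blister.cavity_area", problems)
    unpacked = bool(blis.get("unpacked", False))
    k_perm = None
    wvtr = None
    if "k_perm" in blis:
        k_perm = _parse_quantity(blis["k_perm"], "rate", "blister.k_perm",
                                 problems)
    if "wvtr" in blis:
        w = blis["wvtr"]
        if not isinstance(w, dict):
            problems.append("blister.wvtr: must be a mapping")
        else:
            _check_keys(w, {"value", "donor_rh", "test_temperature"},
                        "blister.wvtr", problems)
            missing = {"value", "donor_rh", "test_temperature"} - set(w)
            if missing:
                problems.append(
                    "blister.wvtr: a WVTR measurement requires value, "
                    f"donor_rh and test_temperature (missing: {sorted(missing)})"
                )
            else:
                wv = _parse_quantity(w["value"], "wvtr", "blister.wvtr.value",
                                     problems)
                dr = _parse_quantity(w["donor_rh"], "fraction",
                                     "blister.wvtr.donor_rh", problems)
                tt = _parse_quantity(w["test_temperature"], "temperature",
                                     "blister.wvtr.test_temperature", problems)
                if None not in (wv, dr, tt):
                    try:
                        wvtr = rp.WvtrMeasurement(wv, dr, tt)
                    except ValueError as exc:
                        problems.append(f"blister.wvtr: {exc}")
    if k_perm is None and wvtr is None and not unpacked:
        problems.append("blister: either k_perm or wvtr must be given")

    tablet = None
    if "tablet" in doc and doc["tablet"] is not None:
        tab = doc["tablet"]
        if not isinstance(tab, dict):
            problems.append("tablet: must be a mapping")
            tab = {}
        _check_keys(tab, {"dry_mass", "monolayer_load", "c_gab", "k_gab",
                          "sorption_rate", "sorption_rate_table",
                          "initial_load"}, "tablet", problems)
        dry = _parse_quantity(tab.get("dry_mass", "nan kg"), "mass",
                              "tablet.dry_mass", problems)
        wm = _parse_quantity(tab.get("monolayer_load", "nan g/g"), "load",
                             "tablet.monolayer_load", problems)
        c_gab = _parse_quantity(tab.get("c_gab", float("nan")), "dimensionless",
                                "tablet.c_gab", problems)
        k_gab = _parse_quantity(tab.get("k_gab", float("nan")), "dimensionless",
                                "tablet.k_gab", problems)
        if "sorption_rate_table" in tab:
            tbl = tab["sorption_rate_table"]
            rate = []
            if not isinstance(tbl, list):
                problems.append("tablet.sorption_rate_table: must be a list")
            else:
                for i, row in enumerate(tbl):
                    r = _parse_quantity(row.get("rh"), "fraction",
                                        f"tablet.sorption_rate_table[{i}].rh",
                                        problems)
                    k = _parse_quantity(row.get("k"), "rate",
                                        f"tablet.sorption_rate_table[{i}].k",
                                        problems)
                    if None not in (r, k):
                        rate.append((r, k))
        else:
            rate = _parse_quantity(tab.get("sorption_rate", "0 1/s"), "rate",
                                   "tablet.sorption_rate", problems)
        init_load = tab.get("initial_load", rp.EQUILIBRIUM_SENTINEL)
        if init_load != rp.EQUILIBRIUM_SENTINEL:
            init_load = _parse_quantity(init_load, "load",
                                        "tablet.initial_load", problems)
        if not problems and None not in (dry, wm, c_gab, k_gab):
            try:
                tablet = rp.TabletSpec(
                    dry_mass=dry,
                    isotherm=rp.GabIsotherm(wm, c_gab, k_gab),
                    sorption_rate=rate,
                    initial_load=init_load,
                )
            except ValueError as exc:
                problems.append(f"tablet: {exc}")

    degradation = None
    if "drug" in doc and doc["drug"] is not None:
        drug = doc["drug"]
        if not isinstance(drug, dict):
            problems.append("drug: must be a mapping")
            drug = {}
        _check_keys(drug, {"molar_mass", "mass", "stoichiometric_factor",
                           "pre_exponential", "activation_energy",
                           "humidity_factor", "arrhenius_sign",
                           "rh_mode"}, "drug", problems)
        md = _parse_quantity(drug.get("molar_mass", "nan g/mol"), "molar_mass",
                             "drug.molar_mass", problems)
        dm = _parse_quantity(drug.get("mass", "nan kg"), "mass", "drug.mass",
                             problems)
        nu = _parse_quantity(drug.get("stoichiometric_factor", 1.0),
                             "dimensionless", "drug.stoichiometric_factor",
                             problems)
        k0 = _parse_quantity(drug.get("pre_exponential", "nan 1/s"), "rate",
                             "drug.pre_exponential", problems)
        ea = _parse_quantity(drug.get("activation_energy", "nan J/mol"),
                             "energy_molar", "drug.activation_energy", problems)
        b = _parse_quantity(drug.get("humidity_factor", float("nan")),
                            "dimensionless", "drug.humidity_factor", problems)
        sign = drug.get("arrhenius_sign", -1)
        if sign not in (-1, 1):
            problems.append(f"drug.arrhenius_sign: must be -1 or 1, got {sign!r}")
        if not problems and None not in (md, dm, nu, k0, ea, b):
            try:
                degradation = rp.DegradationSpec(
                    drug_molar_mass=md, drug_mass=dm, pre_exponential=k0,
                    activation_energy=ea, humidity_factor=b,
                    stoichiometric_factor=nu, arrhenius_sign=sign,
                )
            except ValueError as exc:
                problems.append(f"drug: {exc}")

    solver_settings = _parse_solver_section(doc.get("solver"), problems)

    if problems:
        raise SchemaError(problems)

    rh_mode = "cavity"
    if "drug" in doc and isinstance(doc["drug"], dict):
        rh_mode = doc["drug"].get("rh_mode", "cavity")

    try:
        scenario = Scenario(
            temperature=temperature,
            ambient_rh=ambient_rh,
            initial_cavity_rh=initial_rh,
            geometry=rp.BlisterGeometry(volume, area),
            k_perm=k_perm,
            wvtr=wvtr,
            tablet=tablet,
            degradation=degradation,
            horizon=horizon,
            saturation_pressure=p_sat,
            unpacked=unpacked,
            degradation_rh_mode=rh_mode,
        )
    except ValueError as exc:
        raise SchemaError([str(exc)]) from None

    _plausibility_checks(scenario)
    return scenario, solver_settings


def _parse_solver_section(raw, problems: list[str]) -> SolverSettings:
    if raw is None:
        return SolverSettings()
    if not isinstance(raw, dict):
        problems.append("solver: must be a mapping")
        return SolverSettings()
    _check_keys(raw, {"step_criterion", "convergence_limit",
                      "max_iterations_per_step", "output_interval",
                      "fast_process_threshold"}, "solver", problems)
    kwargs = {}
    if "step_criterion" in raw:
        kwargs["step_criterion"] = _parse_quantity(
            raw["step_criterion"], "dimensionless", "solver.step_criterion",
            problems)
    if "convergence_limit" in raw:
        kwargs["convergence_limit"] = _parse_quantity(
            raw["convergence_limit"], "dimensionless",
            "solver.convergence_limit", problems)
    if "max_iterations_per_step" in raw:
        kwargs["max_iterations_per_step"] = int(raw["max_iterations_per_step"])
    if "output_interval" in raw:
        kwargs["output_interval"] = _parse_quantity(
            raw["output_interval"], "time", "solver.output_interval", problems)
    if "fast_process_threshold" in raw:
        kwargs["fast_process_threshold"] = _parse_quantity(
            raw["fast_process_threshold"], "dimensionless",
            "solver.fast_process_threshold", problems)
    if any(v is None for v in kwargs.values()):
        return SolverSettings()
    try:
        return SolverSettings(**kwargs)
    except ValueError as exc:
        problems.append(f"solver: {exc}")
        return SolverSettings()


def _plausibility_checks(scenario: Scenario) -> None:
    """Warn on parameter combinations that yield implausible kinetics."""
    deg = scenario.degradation
    if deg is None or deg.pre_exponential == 0:
        return
    k = rp.degradation_rate(deg, scenario.temperature, scenario.ambient_rh)
    if k > 0:
        half_life_years = math.log(2) / k / (365 * 86400)
        if half_life_years > 1e6 or half_life_years < 1e-6:
            warnings.warn(
                f"degradation parameters yield a half-life of "
                f"{half_life_years:.3g} years at the ambient condition; the "
                "pre-exponential factor and the sign of the activation-energy "
                "exponent are mutually inconsistent at this magnitude — check "
                "whether the pre-exponential exponent should be read with the "
                "opposite sign (a 'reinterpreted' variant)",
                ParameterPlausibilityWarning,
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# saving (lossless round trip)


def scenario_to_dict(scenario: Scenario) -> dict:
    """Serialize a scenario to the YAML schema (SI units throughout)."""
    env = {
        "temperature": f"{scenario.temperature!r} K",
        "ambient_rh": float(scenario.ambient_rh),
        "initial_cavity_rh": float(scenario.initial_cavity_rh),
        "horizon": f"{scenario.horizon!r} s",
    }
    if scenario.saturation_pressure is not None:
        env["saturation_pressure"] = f"{scenario.saturation_pressure!r} Pa"
    blis = {
        "cavity_volume": f"{scenario.geometry.cavity_volume!r} m^3",
        "cavity_area": f"{scenario.geometry.cavity_area!r} m^2",
    }
    if scenario.unpacked:
        blis["unpacked"] = True
    if scenario.k_perm is not None:
        blis["k_perm"] = f"{scenario.k_perm!r} 1/s"
    elif scenario.wvtr is not None:
        blis["wvtr"] = {
            "value": f"{scenario.wvtr.wvtr!r} kg/m^2/s",
            "donor_rh": float(scenario.wvtr.donor_rh),
            "test_temperature": f"{scenario.wvtr.test_temperature!r} K",
        }
    doc = {"schema_version": SCHEMA_VERSION, "environment": env,
           "blister": blis}
    tab = scenario.tablet
    if tab is not None:
        tdict = {
            "dry_mass": f"{tab.dry_mass!r} kg",
            "monolayer_load": f"{tab.isotherm.monolayer_load!r} g/g",
            "c_gab": float(tab.isotherm.c_gab),
            "k_gab": float(tab.isotherm.k_gab),
        }
        if isinstance(tab.sorption_rate, tuple):
            tdict["sorption_rate_table"] = [
                {"rh": float(r), "k": f"{k!r} 1/s"} for r, k in tab.sorption_rate
            ]
        else:
            tdict["sorption_rate"] = f"{tab.sorption_rate!r} 1/s"
        if tab.initial_load == rp.EQUILIBRIUM_SENTINEL:
            tdict["initial_load"] = rp.EQUILIBRIUM_SENTINEL
        else:
            tdict["initial_load"] = f"{tab.initial_load!r} g/g"
        doc["tablet"] = tdict
    deg = scenario.degradation
    if deg is not None:
        doc["drug"] = {
            "molar_mass": f"{deg.drug_molar_mass!r} g/mol",
            "mass": f"{deg.drug_mass!r} kg",
            "stoichiometric_factor": float(deg.stoichiometric_factor),
            "pre_exponential": f"{deg.pre_exponential!r} 1/s",
            "activation_energy": f"{deg.activation_energy!r} J/mol",
            "humidity_factor": float(deg.humidity_factor),
            "arrhenius_sign": int(deg.arrhenius_sign),
            "rh_mode": scenario.degradation_rh_mode,
        }
    return doc


def settings_to_dict(settings: SolverSettings) -> dict:
    return {
        "step_criterion": float(settings.step_criterion),
        "convergence_limit": float(settings.convergence_limit),
        "max_iterations_per_step": int(settings.max_iterations_per_step),
        "output_interval": f"{settings.output_interval!r} s",
        "fast_process_threshold": float(settings.fast_process_threshold),
    }


def save_scenario(scenario: Scenario, settings: SolverSettings, path) -> None:
    """Write a scenario + settings back to YAML (inverse of load_scenario)."""
    doc = scenario_to_dict(scenario)
    doc["solver"] = settings_to_dict(settings)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def example_config_path(name: str) -> Path:
    """Path of a shipped example configuration (without the .yaml suffix)."""
    ref = resources.files("blisterstab") / "data" / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return Path(p)
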