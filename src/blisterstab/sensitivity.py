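"""Discretization sensitivity: residuals against a fine-reference solution.

The engine has two discretization knobs — the time-step criterion ``sigma``
and the per-step convergence limit ``epsilon``.  This module quantifies
their influence the way such studies are usually presented: simulate the
same scenario at a sequence of coarser levels, interpolate each coarse
trajectory onto the time grid of a reference solution computed at a
distinctly finer level, and report the residual time series (and their
maxima) for cavity humidity, sorbed water mass and drug content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .solver import Scenario, SolverSettings, Trajectory, simulate

__all__ = ["SensitivityReport", "reference_solution", "residual_sweep"]

_VARIABLES = ("cavity_rh", "sorbed_mass", "drug_content_pct")


@dataclass
class SensitivityReport:
    """Residual trajectories of coarse settings against a fine reference.

    `residuals` maps level -> variable -> signed residual array on the
    reference time grid; `max_abs_residuals` summarizes each as the maximum
    absolute value.  Variables whose scenario lacks the corresponding
    process (e.g. drug content without a degradation spec) are omitted.
    """

    parameter: str  # "sigma" or "eps"
    levels: tuple[float, ...]
    time: np.ndarray
    residuals: dict[float, dict[str, np.ndarray]]
    max_abs_residuals: dict[float, dict[str, float]] = field(default_factory=dict)
    reference_settings: SolverSettings | None = None

    def __post_init__(self) -> None:
        if not self.max_abs_residuals:
            self.max_abs_residuals = {
                lev: {var: float(np.max(np.abs(r))) for var, r in vars_.items()}
                for lev, vars_ in self.residuals.items()
            }

    def to_tidy_frame(self) -> pd.DataFrame:
        """Tidy (level, time_s, variable, residual) table."""
        rows = []
        for lev, vars_ in self.residuals.items():
            for var, r in vars_.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "level": lev,
                            "time_s": self.time,
                            "variable": var,
                            "residual": r,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> dict:
        return {
            "parameter": self.parameter,
            "levels": list(self.levels),
            "max_abs_residuals": {
                str(lev): vars_ for lev, vars_ in self.max_abs_residuals.items()
            },
        }


@lru_cache(maxsize=32)
def _cached_run(scenario: Scenario, settings: SolverSettings) -> Trajectory:
    return simulate(scenario, settings)


def reference_solution(
    scenario: Scenario,
    fine_sigma: float,
    fine_eps: float,
    output_interval: float | None = None,
) -> Trajectory:
    """Simulate at fine discretization settings; cached and reused.

    `fine_sigma` must be strictly below every level it will be compared
    against (checked by :func:`residual_sweep`).
    """
    settings = SolverSettings(
        step_criterion=fine_sigma,
        convergence_limit=fine_eps,
        output_interval=output_interval
        if output_interval is not None
        else SolverSettings().output_interval,
    )
    return _cached_run(scenario, settings)


def _interp_onto(t_ref: np.ndarray, traj: Trajectory, var: str) -> np.ndarray:
    return np.interp(t_ref, traj.time, getattr(traj, var))


def residual_sweep(
    scenario: Scenario,
    levels,
    which: str = "sigma",
    base_settings: SolverSettings | None = None,
    reference_level: float | None = None,
) -> SensitivityReport:
    """Residuals of coarse `which` levels against a fine reference.

    Parameters
    ----------
    scenario
        The scenario to study.
    levels
        >= 2 levels of the swept parameter (e.g. ``[1e-1, 1e-2, 1e-3]``).
    which
        ``"sigma"`` sweeps the time-step criterion at the base convergence
        limit; ``"eps"`` sweeps the convergence limit at the base step
        criterion.
    base_settings
        Settings holding the non-swept parameter (defaults to the package
        defaults).
    reference_level
        Level of the reference run; defaults to one decade below the finest
        compared level.  Must be strictly finer than every compared level.
    """
    levels = tuple(float(x) for x in levels)
    if len(levels) < 2:
        raise ValueError(f"need >= 2 levels, got {len(levels)}")
    if which not in ("sigma", "eps"):
        raise ValueError(f"which must be 'sigma' or 'eps', got {which!r}")
    base = base_settings if base_settings is not None else SolverSettings()
    if reference_level is None:
        reference_level = min(levels) / 10.0
    if reference_level >= min(levels):
        raise ValueError(
            f"reference level {reference_level} must be strictly finer than "
            f"the finest compared level {min(levels)}"
        )

    if which == "sigma":
        ref = reference_solution(
            scenario, reference_level, base.convergence_limit,
            output_interval=base.output_interval,
        )
    else:
        ref = reference_solution(
            scenario, base.step_criterion, reference_level,
            output_interval=base.output_interval,
        )

    variables = ["cavity_rh"]
    if scenario.tablet is not None:
        variables.append("sorbed_mass")
    if scenario.degradation is not None:
        variables.append("drug_content_pct")

    residuals: dict[float, dict[str, np.ndarray]] = {}
    errors: dict[float, str] = {}
    for lev in levels:
        if which == "sigma":
            settings = SolverSettings(
                step_criterion=lev,
                convergence_limit=base.convergence_limit,
                output_interval=base.output_interval,
                max_iterations_per_step=base.max_iterations_per_step,
                fast_process_threshold=base.fast_process_threshold,
            )
        else:
            settings = SolverSettings(
                step_criterion=base.step_criterion,
                convergence_limit=lev,
                output_interval=base.output_interval,
                max_iterations_per_step=base.max_iterations_per_step,
                fast_process_threshold=base.fast_process_threshold,
            )
        try:
            traj = _cached_run(scenario, settings)
        except Exception as exc:  # report other levels even if one fails
            errors[lev] = str(exc)
            continue
        residuals[lev] = {
            var: _interp_onto(ref.time, traj, var) - getattr(ref, var)
            for var in variables
        }
    if not residuals:
        raise RuntimeError(
            "every level of the sensitivity sweep failed: "
            + "; ".join(f"{lev}: {msg}" for lev, msg in errors.items())
        )
    report = SensitivityReport(
        parameter=which,
        levels=levels,
        time=ref.time,
        residuals=residuals,
        reference_settings=ref.settings,
    )
    if errors:
        report.summary_errors = errors  # type: ignore[attr-defined]
    return report
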