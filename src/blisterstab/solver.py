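"""Coupled mass-balance engine for a blistered tablet.

The cavity headspace links three first-order processes — permeation through
the foil, sorption by the tablet, hydrolytic degradation of the drug —
through a single water mass balance:

    m_tot = m_vap + m_sor + m_deg

Each process is integrated exactly over a time step with the first-order
increment formula, but the limits of sorption and degradation depend on the
cavity humidity, which itself follows from the balance.  Every step is
therefore solved by fixed-point iteration: increments are recomputed at the
current humidity estimate until the relative change of every compartment
mass falls below the convergence limit.

Step sizes are selected dynamically from the fastest non-equilibrated rate
constant so that one step traverses a fixed fraction (the step criterion
``sigma``) of that process's remaining distance to equilibrium:

    dt = -ln(1 - sigma) / k_fast

When the tablet's sorption kinetics are orders of magnitude faster than
every other process, stepping at the sorption time scale is both wasteful
and unnecessary — the tablet then simply tracks its isotherm.  In that
regime (rate-constant ratio above ``fast_process_threshold``) the solver
treats sorption as instantaneously equilibrated and keys the step size to
the next-fastest process.

A note on the iteration scheme: the tablet's moisture buffer is typically
*thousands* of times larger than the vapor capacity of the headspace
(d m_sor/d rh >> d m_vap/d rh), so plain successive substitution of the
balance diverges.  The solver therefore applies an analytic under-relaxation
factor ``omega = 1 / (1 + G)`` where ``G`` is the local feedback gain
computed from the isotherm slope; this recovers plain substitution when the
coupling is weak and converges in a handful of iterations when it is stiff.
The converged state is independent of the relaxation path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import rate_processes as rp
from .moist_air import GasVolume, relative_humidity, vapor_mass

__all__ = [
    "Scenario",
    "SolverSettings",
    "CompartmentState",
    "Trajectory",
    "ConvergenceError",
    "VaporDepletionWarning",
    "select_time_step",
    "advance_step",
    "simulate",
    "drug_content_series",
]

#: Relative gap (w.r.t. the process's own scale) below which a process is
#: treated as equilibrated and no longer drives the step size.
_EQUILIBRATED_RTOL = 1e-9


class ConvergenceError(RuntimeError):
    """Per-step fixed-point iteration failed to reach the convergence limit."""

    def __init__(self, message: str, time: float, iterations: int):
        super().__init__(message)
        self.time = time
        self.iterations = iterations


class VaporDepletionWarning(UserWarning):
    """Sorption/degradation demanded more water than the vapor phase holds."""


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of one blister–tablet–drug–environment system.

    Parameters
    ----------
    temperature
        Storage temperature, K.
    ambient_rh, initial_cavity_rh
        Relative humidity (fraction) outside the blister and in the cavity
        at t = 0.
    geometry
        Cavity volume and permeable area.
    k_perm
        Permeation rate constant in 1/s, or None if `wvtr` is given.
    wvtr
        A WVTR measurement to be converted to `k_perm`; ignored when
        `k_perm` is given explicitly.
    tablet, degradation
        Optional tablet and drug-degradation specifications; omit the tablet
        for empty-blister runs.
    horizon
        Total simulated duration, s.
    saturation_pressure
        Optional pinned saturation vapor pressure, Pa (overrides the
        built-in correlation, e.g. to use a tabulated steam-table value).
    unpacked
        If True the cavity humidity is pinned to the ambient humidity — the
        "unpacked tablet" reference mode (infinitely permeable packaging).
    degradation_rh_mode
        ``"cavity"`` (default): the degradation rate sees the cavity
        humidity.  ``"tablet"``: it sees the tablet's instantaneous water
        activity (inverse isotherm of the current moisture load).
    """

    temperature: float
    ambient_rh: float
    initial_cavity_rh: float
    geometry: rp.BlisterGeometry
    k_perm: float | None = None
    wvtr: rp.WvtrMeasurement | None = None
    tablet: rp.TabletSpec | None = None
    degradation: rp.DegradationSpec | None = None
    horizon: float = 86400.0
    saturation_pressure: float | None = None
    unpacked: bool = False
    degradation_rh_mode: str = "cavity"

    def __post_init__(self) -> None:
        for name in ("ambient_rh", "initial_cavity_rh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.horizon > 0:
            raise ValueError(f"horizon must be > 0, got {self.horizon}")
        if self.k_perm is None and self.wvtr is None and not self.unpacked:
            raise ValueError("either k_perm or wvtr must be given")
        if self.k_perm is not None and self.k_perm < 0:
            raise ValueError(f"k_perm must be >= 0, got {self.k_perm}")
        if self.degradation_rh_mode not in ("cavity", "tablet"):
            raise ValueError(
                f"degradation_rh_mode must be 'cavity' or 'tablet', "
                f"got {self.degradation_rh_mode!r}"
            )
        if self.degradation_rh_mode == "tablet" and self.tablet is None:
            raise ValueError("degradation_rh_mode='tablet' requires a tablet")

    @property
    def gas(self) -> GasVolume:
        return GasVolume(
            self.geometry.cavity_volume,
            self.temperature,
            saturation_pressure=self.saturation_pressure,
        )

    def permeation_rate(self) -> float:
        """Permeation rate constant in 1/s (converting WVTR if needed)."""
        if self.unpacked:
            return math.inf
        if self.k_perm is not None:
            return self.k_perm
        return rp.kperm_from_wvtr(
            self.wvtr, self.geometry, saturation_pressure=self.saturation_pressure
        )


@dataclass(frozen=True)
class SolverSettings:
    """Discretization and convergence parameters of the engine.

    ``step_criterion`` (sigma) is the fraction of equilibrium the fastest
    process traverses in one step; ``convergence_limit`` (epsilon) the
    maximum permitted relative change of any compartment mass between
    fixed-point iterations; ``fast_process_threshold`` the rate-constant
    ratio above which sorption is treated as instantaneously equilibrated.
    ``output_interval`` only controls recording, never the integration.
    """

    step_criterion: float = 1e-2
    convergence_limit: float = 1e-8
    max_iterations_per_step: int = 10_000
    output_interval: float = 86400.0
    fast_process_threshold: float = 1e3

    def __post_init__(self) -> None:
        if not 0.0 < self.step_criterion < 1.0:
            raise ValueError(
                f"step_criterion must lie in (0, 1), got {self.step_criterion}"
            )
        if not self.convergence_limit > 0:
            raise ValueError(
                f"convergence_limit must be > 0, got {self.convergence_limit}"
            )
        if self.max_iterations_per_step < 1:
            raise ValueError("max_iterations_per_step must be >= 1")
        if not self.output_interval > 0:
            raise ValueError(f"output_interval must be > 0, got {self.output_interval}")
        if not self.fast_process_threshold > 1:
            raise ValueError("fast_process_threshold must be > 1")


@dataclass(frozen=True)
class CompartmentState:
    """Time-stamped water masses of the three compartments (all kg)."""

    time: float
    vapor_mass: float
    sorbed_mass: float
    degraded_water: float
    cumulative_permeated: float
    cavity_rh: float


def select_time_step(sigma: float, k_fast: float, fallback: float = math.inf) -> float:
    """Dynamic step size: one step covers fraction `sigma` of equilibrium.

    ``dt = -ln(1 - sigma) / k_fast`` for the fastest rate constant.  With
    ``k_fast = 0`` (no finite fast process) the `fallback` — normally the
    output interval — is returned.
    """
    if not 0.0 < sigma < 1.0:
        raise ValueError(f"sigma must lie in (0, 1), got {sigma}")
    if k_fast < 0:
        raise ValueError(f"k_fast must be >= 0, got {k_fast}")
    if k_fast == 0.0:
        return fallback
    return -math.log1p(-sigma) / k_fast


class _Context:
    """Scenario unpacked into plain floats for the inner loop."""

    __slots__ = (
        "scenario", "settings", "gas", "capacity", "k_perm", "m_env",
        "tablet", "deg", "deg_capacity", "k_deg_base", "B", "T",
        "rh_mode_tablet", "warn_count",
    )

    def __init__(self, scenario: Scenario, settings: SolverSettings):
        self.scenario = scenario
        self.settings = settings
        self.gas = scenario.gas
        self.capacity = self.gas.vapor_capacity
        self.k_perm = scenario.permeation_rate()
        self.m_env = vapor_mass(scenario.ambient_rh, self.gas)
        self.tablet = scenario.tablet
        self.deg = scenario.degradation
        if self.deg is not None:
            self.deg_capacity = rp.degradation_capacity(self.deg)
            # k_deg(rh) = k_deg_base * exp(B * rh)
            self.k_deg_base = rp.degradation_rate(self.deg, scenario.temperature, 0.0)
            self.B = self.deg.humidity_factor
        else:
            self.deg_capacity = 0.0
            self.k_deg_base = 0.0
            self.B = 0.0
        self.T = scenario.temperature
        self.rh_mode_tablet = scenario.degradation_rh_mode == "tablet"
        self.warn_count = 0

    def k_deg_at(self, rh: float) -> float:
        return self.k_deg_base * math.exp(self.B * min(max(rh, 0.0), 1.0))

    def sorption_limit_at(self, rh: float) -> float:
        rh = min(max(rh, 0.0), 1.0)
        return rp.gab_load(self.tablet.isotherm, rh) * self.tablet.dry_mass

    def initial_state(self) -> CompartmentState:
        sc = self.scenario
        rh0 = sc.ambient_rh if sc.unpacked else sc.initial_cavity_rh
        m_v = vapor_mass(rh0, self.gas)
        if self.tablet is None:
            m_s = 0.0
        elif self.tablet.initial_load == rp.EQUILIBRIUM_SENTINEL:
            m_s = self.sorption_limit_at(rh0)
        else:
            m_s = self.tablet.initial_load * self.tablet.dry_mass
        return CompartmentState(0.0, m_v, m_s, 0.0, 0.0, rh0)


def _rel_change(new: float, old: float) -> float:
    scale = max(abs(new), abs(old))
    if scale == 0.0:
        return 0.0
    return abs(new - old) / scale


def _advance(
    ctx: _Context,
    state: CompartmentState,
    dt: float,
    sorption_instant: bool,
) -> tuple[CompartmentState, int]:
    """One converged time step; returns (new state, iterations used)."""
    st = ctx.settings
    m_v, m_s, m_d = state.vapor_mass, state.sorbed_mass, state.degraded_water
    cap = ctx.capacity
    eps = st.convergence_limit

    if ctx.scenario.unpacked:
        # Cavity pinned to ambient humidity: no coupling, single pass.
        phi = ctx.scenario.ambient_rh
        d_sor = 0.0
        if ctx.tablet is not None:
            L = ctx.sorption_limit_at(phi)
            if sorption_instant:
                d_sor = L - m_s
            else:
                k_sor = ctx.tablet.sorption_rate_at(phi)
                d_sor = (L - m_s) * -math.expm1(-k_sor * dt)
        d_deg = 0.0
        if ctx.deg is not None:
            phi_deg = _deg_rh(ctx, phi, m_s + d_sor)
            k_deg = ctx.k_deg_at(phi_deg)
            d_deg = (ctx.deg_capacity - m_d) * -math.expm1(-k_deg * dt)
        m_v_new = ctx.m_env
        d_perm = m_v_new - m_v + d_sor + d_deg
        new = CompartmentState(
            state.time + dt, m_v_new, m_s + d_sor, m_d + d_deg,
            state.cumulative_permeated + d_perm, phi,
        )
        return new, 1

    perm_f = -math.expm1(-ctx.k_perm * dt) if ctx.k_perm < math.inf else 1.0
    have_tab = ctx.tablet is not None
    have_deg = ctx.deg is not None

    # Fixed-point iteration on the end-of-step cavity humidity: sorption and
    # degradation increments are evaluated at the current humidity estimate,
    # permeation sees the vapor mass after their drawdown, and the balance
    # returns the implied humidity.  The estimate is under-relaxed with the
    # analytic feedback gain (isotherm slope over vapor capacity), which
    # makes the update Newton-like; the converged state does not depend on
    # the relaxation.
    phi_est = state.cavity_rh
    prev = (m_v, m_s, m_d)
    for it in range(1, st.max_iterations_per_step + 1):
        phi_c = min(max(phi_est, 0.0), 1.0)

        gain = 0.0
        if have_tab:
            L = ctx.sorption_limit_at(phi_c)
            if sorption_instant:
                sor_f = 1.0
            else:
                k_sor = ctx.tablet.sorption_rate_at(phi_c)
                sor_f = -math.expm1(-k_sor * dt)
            d_sor = (L - m_s) * sor_f
            gain += (
                sor_f
                * rp.gab_slope(ctx.tablet.isotherm, phi_c)
                * ctx.tablet.dry_mass
                / cap
                * (1.0 - perm_f)
            )
        else:
            d_sor = 0.0

        if have_deg:
            phi_deg = _deg_rh(ctx, phi_c, m_s + d_sor)
            k_deg = ctx.k_deg_at(phi_deg)
            e = math.exp(-k_deg * dt)
            d_deg = (ctx.deg_capacity - m_d) * (1.0 - e)
            if not ctx.rh_mode_tablet:
                gain += (
                    (ctx.deg_capacity - m_d) * e * dt * ctx.B * k_deg
                    / cap * (1.0 - perm_f)
                )
        else:
            d_deg = 0.0

        start_vap = m_v - d_sor - d_deg
        if start_vap < 0.0:
            start_vap = 0.0
        d_perm = (ctx.m_env - start_vap) * perm_f
        m_v_new = m_v + d_perm - d_sor - d_deg
        phi_new = m_v_new / cap
        phi_est = phi_est + (phi_new - phi_est) / (1.0 + gain)

        cur = (m_v_new, m_s + d_sor, m_d + d_deg)
        if (
            _rel_change(cur[0], prev[0]) <= eps
            and _rel_change(cur[1], prev[1]) <= eps
            and _rel_change(cur[2], prev[2]) <= eps
        ):
            break
        prev = cur
    else:
        raise ConvergenceError(
            f"fixed-point iteration did not reach the convergence limit "
            f"{eps} within {st.max_iterations_per_step} iterations "
            f"(t = {state.time:.6g} s, dt = {dt:.6g} s)",
            time=state.time,
            iterations=st.max_iterations_per_step,
        )

    if m_v_new < 0.0:
        ctx.warn_count += 1
        warnings.warn(
            f"vapor phase depleted at t = {state.time + dt:.6g} s "
            f"(computed vapor mass {m_v_new:.3e} kg clamped to 0); "
            "moisture-starved regime, outside model validity",
            VaporDepletionWarning,
            stacklevel=3,
        )
        m_v_new = 0.0

    new = CompartmentState(
        state.time + dt,
        m_v_new,
        m_s + d_sor,
        min(m_d + d_deg, ctx.deg_capacity) if have_deg else 0.0,
        state.cumulative_permeated + d_perm,
        m_v_new / cap,
    )
    return new, it


def _deg_rh(ctx: _Context, cavity_rh: float, sorbed: float) -> float:
    """Humidity the degradation rate sees (cavity RH or tablet activity)."""
    if not ctx.rh_mode_tablet:
        return cavity_rh
    load = sorbed / ctx.tablet.dry_mass
    try:
        return rp.gab_activity(ctx.tablet.isotherm, load)
    except ValueError:
        return 1.0


def _active_rates(
    ctx: _Context, state: CompartmentState
) -> tuple[list[float], bool]:
    """Rate constants of non-equilibrated processes + sorption-shortcut flag.

    Sorption is treated as instantaneous when its rate constant exceeds
    ``fast_process_threshold`` times both the fastest other active rate
    constant and the recording rate (1 / output interval) — i.e. when the
    sorption transient can neither influence the step budget nor be
    resolved in the output.
    """
    rates: list[float] = []
    if not ctx.scenario.unpacked and ctx.k_perm > 0:
        if abs(ctx.m_env - state.vapor_mass) > _EQUILIBRATED_RTOL * ctx.capacity:
            rates.append(ctx.k_perm)
    if ctx.deg is not None:
        k_deg = ctx.k_deg_at(state.cavity_rh)
        if k_deg > 0 and ctx.deg_capacity - state.degraded_water > (
            _EQUILIBRATED_RTOL * ctx.deg_capacity
        ):
            rates.append(k_deg)

    sorption_instant = False
    if ctx.tablet is not None:
        k_sor = ctx.tablet.sorption_rate_at(state.cavity_rh)
        gap_scale = max(
            ctx.sorption_limit_at(state.cavity_rh), state.sorbed_mass, ctx.capacity
        )
        gap = abs(ctx.sorption_limit_at(state.cavity_rh) - state.sorbed_mass)
        active = k_sor > 0 and gap > _EQUILIBRATED_RTOL * gap_scale
        floor = max(
            max(rates) if rates else 0.0, 1.0 / ctx.settings.output_interval
        )
        if k_sor > 0 and rates and k_sor > ctx.settings.fast_process_threshold * floor:
            sorption_instant = True
        elif active:
            rates.append(k_sor)
    return rates, sorption_instant


def advance_step(
    state: CompartmentState,
    scenario: Scenario,
    settings: SolverSettings,
    dt: float,
) -> CompartmentState:
    """Advance one converged time step of length `dt` from `state`.

    Fixed-point iteration of the per-step mass balance: permeation toward
    the ambient limit, sorption toward the isotherm limit at the current
    cavity humidity, degradation at the humidity-corrected Arrhenius rate,
    then vapor mass from the balance — repeated until the relative change
    of every compartment mass is below the convergence limit.
    """
    ctx = _Context(scenario, settings)
    _, sorption_instant = _active_rates(ctx, state)
    new, _ = _advance(ctx, state, dt, sorption_instant)
    return new


@dataclass
class Trajectory:
    """Recorded time series of a simulation on the output grid.

    All mass series are in kg; `tablet_load` in g water per g dry solid;
    `drug_content_pct` in percent of the initial drug load (NaN when the
    scenario has no degradation spec).  `stats` carries solver diagnostics
    (step and iteration counts, warnings).
    """

    time: np.ndarray
    vapor_mass: np.ndarray
    sorbed_mass: np.ndarray
    degraded_water: np.ndarray
    cumulative_permeated: np.ndarray
    cavity_rh: np.ndarray
    tablet_load: np.ndarray
    drug_content_pct: np.ndarray
    scenario: Scenario
    settings: SolverSettings
    stats: dict = field(default_factory=dict)

    @property
    def states(self) -> list[CompartmentState]:
        return [
            CompartmentState(
                float(t), float(v), float(s), float(d), float(p), float(r)
            )
            for t, v, s, d, p, r in zip(
                self.time, self.vapor_mass, self.sorbed_mass,
                self.degraded_water, self.cumulative_permeated, self.cavity_rh,
            )
        ]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "cavity_rh": self.cavity_rh,
                "vapor_mass_kg": self.vapor_mass,
                "sorbed_mass_kg": self.sorbed_mass,
                "degraded_water_kg": self.degraded_water,
                "cumulative_permeated_kg": self.cumulative_permeated,
                "tablet_load_g_per_g": self.tablet_load,
                "drug_content_pct": self.drug_content_pct,
            }
        )

    def to_csv(self, path, metadata_path=None) -> None:
        """Write the trajectory as CSV, plus an optional JSON sidecar."""
        self.to_frame().to_csv(path, index=False)
        if metadata_path is not None:
            import json

            from .config import scenario_to_dict, settings_to_dict

            meta = {
                "scenario": scenario_to_dict(self.scenario),
                "solver": settings_to_dict(self.settings),
                "stats": self.stats,
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    def mass_balance_error(self) -> np.ndarray:
        """Relative mass-balance defect at each recorded state."""
        total = self.vapor_mass + self.sorbed_mass + self.degraded_water
        expected = total[0] + self.cumulative_permeated - self.cumulative_permeated[0]
        scale = np.maximum(np.abs(total), np.abs(expected))
        err = np.abs(total - expected)
        return np.divide(err, scale, out=np.zeros_like(err), where=scale > 0)

    def validate(self) -> None:
        """Assert the structural invariants of a trajectory."""
        n = len(self.time)
        for name in (
            "vapor_mass", "sorbed_mass", "degraded_water",
            "cumulative_permeated", "cavity_rh", "tablet_load",
            "drug_content_pct",
        ):
            if len(getattr(self, name)) != n:
                raise AssertionError(f"series {name} has wrong length")
        if not np.all(np.diff(self.time) > 0):
            raise AssertionError("time not strictly increasing")
        if not np.all(np.diff(self.degraded_water) >= -1e-18):
            raise AssertionError("degraded water decreased")
        dc = self.drug_content_pct
        if not np.all(np.isnan(dc)) and not np.all(np.diff(dc) <= 1e-12):
            raise AssertionError("drug content increased")
        tol = self.settings.convergence_limit
        if np.any(self.mass_balance_error() > tol):
            raise AssertionError("mass balance violated beyond convergence limit")


def drug_content_series(
    traj_or_degraded, deg: rp.DegradationSpec
) -> np.ndarray:
    """Drug content (% of initial load) from the degraded-water series.

    Accepts a :class:`Trajectory` or a raw array of consumed water masses.
    Starts at 100, non-increasing, bounded below by 0.
    """
    if isinstance(traj_or_degraded, Trajectory):
        consumed = traj_or_degraded.degraded_water
    else:
        consumed = np.asarray(traj_or_degraded, dtype=float)
    cap = rp.degradation_capacity(deg)
    if deg.drug_mass == 0 or cap == 0:
        return np.full_like(consumed, 100.0)
    frac = np.clip(consumed / cap, 0.0, 1.0)
    return 100.0 * (1.0 - frac)


def simulate(scenario: Scenario, settings: SolverSettings | None = None) -> Trajectory:
    """Run the coupled simulation over the scenario horizon.

    Steps are selected dynamically from the fastest non-equilibrated rate
    constant; states are recorded on the uniform output grid (plus the
    horizon endpoint) by linear interpolation between the bracketing
    integration steps, so the recorded values are independent of the
    output interval.
    """
    if settings is None:
        settings = SolverSettings()
    ctx = _Context(scenario, settings)
    state = ctx.initial_state()

    horizon = scenario.horizon
    out_dt = settings.output_interval
    n_out = int(math.floor(horizon / out_dt + 1e-9))
    grid = [i * out_dt for i in range(n_out + 1)]
    if grid[-1] < horizon * (1 - 1e-12):
        grid.append(horizon)
    rec_times: list[float] = []
    rec: list[tuple[float, float, float, float, float]] = []

    def _record(t, s_prev: CompartmentState, s_new: CompartmentState) -> None:
        if s_new.time == s_prev.time:
            w = 0.0
        else:
            w = (t - s_prev.time) / (s_new.time - s_prev.time)
        rec_times.append(t)
        rec.append(
            (
                s_prev.vapor_mass + w * (s_new.vapor_mass - s_prev.vapor_mass),
                s_prev.sorbed_mass + w * (s_new.sorbed_mass - s_prev.sorbed_mass),
                s_prev.degraded_water
                + w * (s_new.degraded_water - s_prev.degraded_water),
                s_prev.cumulative_permeated
                + w * (s_new.cumulative_permeated - s_prev.cumulative_permeated),
                0.0,  # cavity_rh recomputed from vapor mass below
            )
        )

    _record(0.0, state, state)
    next_idx = 1

    n_steps = 0
    total_iters = 0
    max_iters = 0
    shortcut_steps = 0

    while state.time < horizon * (1 - 1e-12):
        rates, sorption_instant = _active_rates(ctx, state)
        k_fast = max(rates) if rates else 0.0
        dt = select_time_step(settings.step_criterion, k_fast, fallback=out_dt)
        dt = min(dt, horizon - state.time)
        try:
            new, iters = _advance(ctx, state, dt, sorption_instant)
        except ConvergenceError as exc:
            raise ConvergenceError(
                str(exc), time=exc.time, iterations=exc.iterations
            ) from None
        n_steps += 1
        total_iters += iters
        max_iters = max(max_iters, iters)
        if sorption_instant:
            shortcut_steps += 1
        while next_idx < len(grid) and grid[next_idx] <= new.time * (1 + 1e-12):
            _record(min(grid[next_idx], new.time), state, new)
            next_idx += 1
        state = new

    arr = np.array(rec, dtype=float)
    time = np.array(rec_times)
    vapor, sorbed, degd, perm = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    rh = vapor / ctx.capacity
    if scenario.tablet is not None:
        load = sorbed / scenario.tablet.dry_mass
    else:
        load = np.full_like(sorbed, np.nan)
    if scenario.degradation is not None:
        content = drug_content_series(degd, scenario.degradation)
    else:
        content = np.full_like(degd, np.nan)

    stats = {
        "n_steps": n_steps,
        "total_iterations": total_iters,
        "max_iterations_per_step": max_iters,
        "sorption_shortcut_steps": shortcut_steps,
        "vapor_depletion_warnings": ctx.warn_count,
    }
    return Trajectory(
        time=time,
        vapor_mass=vapor,
        sorbed_mass=sorbed,
        degraded_water=degd,
        cumulative_permeated=perm,
        cavity_rh=rh,
        tablet_load=load,
        drug_content_pct=content,
        scenario=scenario,
        settings=settings,
        stats=stats,
    )
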