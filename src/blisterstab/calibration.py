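"""Parameter estimation from experimental-style data.

Three fitters mirror the three rate processes:

* :func:`fit_gab` — bounded nonlinear least squares of the GAB isotherm to
  equilibrium (rh, load) points, with deterministic multistart;
* :func:`fit_sorption_rate` — single-exponential fits of normalized
  dynamic-vapor-sorption uptake curves, pooled across humidity levels when
  the per-level estimates are mutually consistent;
* :func:`fit_degradation_arrhenius` — linear regression of ln k on
  (1/T, rh), which is exact for data generated by the humidity-corrected
  Arrhenius law since the model is linear in those coordinates.

All fitters recover their own generating model exactly on noiseless data;
that round-trip identifiability is part of the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .moist_air import R_GAS
from .rate_processes import GabIsotherm

__all__ = [
    "IsothermPoint",
    "UptakeCurve",
    "DegradationObservation",
    "GabFitResult",
    "SorptionRateFit",
    "ArrheniusFitResult",
    "FitError",
    "DataQualityWarning",
    "fit_gab",
    "fit_sorption_rate",
    "fit_humidity_factor",
    "fit_degradation_arrhenius",
    "read_isotherm_csv",
    "read_uptake_csv",
    "read_degradation_csv",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best_params=None, residual_norm=None):
        super().__init__(message)
        self.best_params = best_params
        self.residual_norm = residual_norm


class DataQualityWarning(UserWarning):
    """Input data violate an expectation of the model beyond noise level."""


@dataclass(frozen=True)
class IsothermPoint:
    """One equilibrium sorption measurement: humidity and moisture load."""

    rh: float
    load: float  # g water / g dry solid

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh < 1.0:
            raise ValueError(f"rh must lie in [0, 1), got {self.rh}")
        if self.load < 0:
            raise ValueError(f"load must be >= 0, got {self.load}")


@dataclass(frozen=True)
class UptakeCurve:
    """A normalized DVS uptake curve at one humidity level.

    `samples` are (time s, X/X_inf) pairs with time strictly increasing and
    the normalized load in [0, 1] up to a small noise tolerance.
    """

    rh: float
    samples: tuple[tuple[float, float], ...]
    noise_tolerance: float = 0.05

    def __post_init__(self) -> None:
        samples = tuple((float(t), float(x)) for t, x in self.samples)
        object.__setattr__(self, "samples", samples)
        if len(samples) < 3:
            raise ValueError(
                f"uptake curve at rh={self.rh} needs >= 3 samples, "
                f"got {len(samples)}"
            )
        times = [t for t, _ in samples]
        if sorted(times) != times or len(set(times)) != len(times):
            raise ValueError("sample times must be strictly increasing")
        tol = self.noise_tolerance
        if any(x < -tol or x > 1 + tol for _, x in samples):
            raise ValueError(
                f"normalized loads must lie in [0, 1] (tolerance {tol})"
            )
        drops = [
            samples[i + 1][1] - samples[i][1] for i in range(len(samples) - 1)
        ]
        if any(d < -tol for d in drops):
            warnings.warn(
                f"uptake curve at rh={self.rh}: normalized load decreases by "
                f"more than the noise tolerance {tol}; data may mix sorption "
                "and desorption",
                DataQualityWarning,
                stacklevel=3,
            )

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples])

    @property
    def loads(self) -> np.ndarray:
        return np.array([x for _, x in self.samples])


@dataclass(frozen=True)
class DegradationObservation:
    """A degradation rate constant measured at one (T, rh) condition."""

    temperature: float  # K
    rh: float
    rate_constant: float  # 1/s

    def __post_init__(self) -> None:
        if not self.rate_constant > 0:
            raise ValueError(
                f"rate_constant must be > 0, got {self.rate_constant}"
            )
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not 0.0 <= self.rh <= 1.0:
            raise ValueError(f"rh must lie in [0, 1], got {self.rh}")


# ---------------------------------------------------------------------------
# GAB isotherm fit

_GAB_BOUNDS = ([1e-6, 1e-4, 1e-4], [10.0, 1e4, 1.0 - 1e-9])

#: Deterministic multistart grid (wm, C, K); the published fitting protocol
#: for GAB isotherms varies, so the fit simply keeps the best of these.
_GAB_STARTS = [
    (0.01, 1.0, 0.5),
    (0.03, 10.0, 0.8),
    (0.05, 100.0, 0.9),
    (0.1, 5.0, 0.7),
    (0.005, 50.0, 0.95),
]


@dataclass
class GabFitResult:
    """Fitted GAB isotherm with least-squares diagnostics."""

    isotherm: GabIsotherm
    residual_norm: float
    stderr: dict[str, float]
    n_points: int
    residual_history: list[float] = field(default_factory=list)

    @property
    def params(self) -> tuple[float, float, float]:
        iso = self.isotherm
        return (iso.monolayer_load, iso.c_gab, iso.k_gab)


def fit_gab(points: Iterable[IsothermPoint]) -> GabFitResult:
    """Fit the GAB isotherm to equilibrium sorption points.

    Bounded nonlinear least squares (trust-region reflective) from five
    deterministic starting guesses; the best converged solution is
    returned.  Requires at least 4 points spanning at least 3 distinct
    humidity values.  Standard errors come from the Gauss-Newton
    approximation of the parameter covariance.
    """
    pts = [p if isinstance(p, IsothermPoint) else IsothermPoint(*p)
           for p in points]
    if len(pts) < 4:
        raise ValueError(f"need >= 4 isotherm points, got {len(pts)}")
    rh = np.array([p.rh for p in pts])
    load = np.array([p.load for p in pts])
    if len(np.unique(rh)) < 3:
        raise ValueError(
            f"need >= 3 distinct rh values, got {len(np.unique(rh))}"
        )

    def residuals(theta):
        wm, c, k = theta
        u = k * rh
        model = wm * c * u / ((1 - u) * (1 - u + c * u))
        return model - load

    best = None
    history: list[float] = []
    for start in _GAB_STARTS:
        try:
            sol = least_squares(residuals, start, bounds=_GAB_BOUNDS,
                                method="trf", xtol=1e-15, ftol=1e-15,
                                gtol=1e-15)
        except Exception:
            continue
        history.append(float(np.linalg.norm(sol.fun)))
        if sol.success and (best is None or history[-1] < np.linalg.norm(best.fun)):
            best = sol
    if best is None:
        raise FitError(
            "GAB fit did not converge from any starting guess",
            best_params=None,
            residual_norm=min(history) if history else None,
        )

    wm, c, k = best.x
    dof = max(len(pts) - 3, 1)
    s2 = float(np.sum(best.fun**2)) / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return GabFitResult(
        isotherm=GabIsotherm(float(wm), float(c), float(k)),
        residual_norm=float(np.linalg.norm(best.fun)),
        stderr={"monolayer_load": float(se[0]), "c_gab": float(se[1]),
                "k_gab": float(se[2])},
        n_points=len(pts),
        residual_history=history,
    )


# ---------------------------------------------------------------------------
# sorption-rate fit


@dataclass
class SorptionRateFit:
    """Per-humidity sorption rate constants and an optional pooled value.

    `per_rh` maps humidity level to (k, standard error).  `pooled` is the
    inverse-variance-weighted mean when the per-level 95 % confidence
    intervals mutually overlap, else None with ``consistent = False`` — the
    tabulated per-humidity form should then be used in scenarios.
    """

    per_rh: dict[float, tuple[float, float]]
    pooled: float | None
    consistent: bool

    def as_table(self) -> tuple[tuple[float, float], ...]:
        """(rh, k) pairs usable as a TabletSpec sorption-rate table."""
        return tuple(sorted((rh, k) for rh, (k, _) in self.per_rh.items()))


def _fit_single_exponential(curve: UptakeCurve) -> tuple[float, float]:
    """Least-squares fit of X/X_inf = 1 - exp(-k t); returns (k, se)."""
    t, y = curve.times, curve.loads
    mask = (y < 1.0) & (t > 0)
    if mask.any():
        k0 = float(np.median(-np.log1p(-np.clip(y[mask], 0, 1 - 1e-12)) / t[mask]))
    else:
        k0 = 1.0 / max(t.max(), 1e-12)
    k0 = max(k0, 1e-300)

    def residuals(logk):
        return -np.expm1(-math.exp(logk[0]) * t) - y

    sol = least_squares(residuals, [math.log(k0)], method="lm",
                        xtol=1e-15, ftol=1e-15)
    if not sol.success:
        raise FitError(
            f"sorption-rate fit failed for curve at rh={curve.rh}",
            best_params=math.exp(sol.x[0]),
            residual_norm=float(np.linalg.norm(sol.fun)),
        )
    k = math.exp(float(sol.x[0]))
    dof = max(len(t) - 1, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    # d(residual)/dk = t * exp(-k t); SE via Gauss-Newton in k (not log k)
    jac_k = t * np.exp(-k * t)
    jtj = float(jac_k @ jac_k)
    se = math.sqrt(s2 / jtj) if jtj > 0 else math.inf
    return k, se


def fit_sorption_rate(curves: Iterable[UptakeCurve]) -> SorptionRateFit:
    """Fit sorption rate constants from normalized uptake curves.

    Each curve is fit to the single-exponential approach to equilibrium.
    When the per-humidity 95 % confidence intervals all overlap pairwise,
    a pooled (inverse-variance weighted) rate constant is returned; when
    they do not, the estimates genuinely depend on humidity and only the
    per-humidity table is usable.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one uptake curve")
    per_rh: dict[float, tuple[float, float]] = {}
    for curve in curves:
        per_rh[curve.rh] = _fit_single_exponential(curve)

    ks = np.array([k for k, _ in per_rh.values()])
    ses = np.array([se for _, se in per_rh.values()])
    z = 1.96
    lo, hi = ks - z * ses, ks + z * ses
    consistent = True
    for i in range(len(ks)):
        for j in range(i + 1, len(ks)):
            if lo[i] > hi[j] or lo[j] > hi[i]:
                consistent = False
    if consistent:
        if np.all(ses > 0) and np.all(np.isfinite(ses)):
            w = 1.0 / ses**2
            pooled = float(np.sum(w * ks) / np.sum(w))
        else:
            pooled = float(np.mean(ks))
    else:
        pooled = None
    return SorptionRateFit(per_rh=per_rh, pooled=pooled, consistent=consistent)


# ---------------------------------------------------------------------------
# humidity-corrected Arrhenius regression


@dataclass
class ArrheniusFitResult:
    """Humidity-corrected Arrhenius parameters from ln-space regression.

    ``ln k = ln k0 + slope_T / T + B * rh`` — `slope_T` is reported as
    fitted; under the standard (negative-exponent) convention the
    activation energy is ``Ea = -slope_T * R``, exposed as
    `activation_energy`.  A positive fitted `slope_T` therefore surfaces as
    a negative activation energy rather than being silently sign-flipped.
    """

    pre_exponential: float  # k0, 1/s
    slope_T: float  # K (coefficient of 1/T)
    humidity_factor: float  # B
    r_squared: float
    stderr: dict[str, float]
    n_obs: int

    @property
    def activation_energy(self) -> float:
        """Ea in J/mol under the negative-exponent convention."""
        return -self.slope_T * R_GAS


def _as_observations(obs) -> list[DegradationObservation]:
    return [
        o if isinstance(o, DegradationObservation) else DegradationObservation(*o)
        for o in obs
    ]


def fit_degradation_arrhenius(
    obs: Iterable[DegradationObservation],
) -> ArrheniusFitResult:
    """Regress ln k on (1/T, rh) — the humidity-corrected Arrhenius fit.

    The model is linear in these coordinates, so noiseless data are
    recovered exactly.  Requires >= 4 observations covering >= 2 distinct
    temperatures and >= 2 distinct humidity levels; a rank-deficient design
    raises a validation error naming the missing axis.
    """
    data = _as_observations(obs)
    if len(data) < 4:
        raise ValueError(f"need >= 4 observations, got {len(data)}")
    T = np.array([o.temperature for o in data])
    rh = np.array([o.rh for o in data])
    if len(np.unique(T)) < 2:
        raise ValueError(
            "need >= 2 distinct temperatures to identify the activation "
            "energy; all observations share one temperature (use "
            "fit_humidity_factor for an isothermal humidity sweep)"
        )
    if len(np.unique(rh)) < 2:
        raise ValueError(
            "need >= 2 distinct relative humidities to identify the "
            "humidity sensitivity factor"
        )
    y = np.log([o.rate_constant for o in data])
    X = np.column_stack([np.ones_like(T), 1.0 / T, rh])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(data) - 3, 1)
    s2 = ss_res / dof
    try:
        cov = np.linalg.inv(X.T @ X) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return ArrheniusFitResult(
        pre_exponential=float(np.exp(beta[0])),
        slope_T=float(beta[1]),
        humidity_factor=float(beta[2]),
        r_squared=r2,
        stderr={"ln_k0": float(se[0]), "slope_T": float(se[1]),
                "humidity_factor": float(se[2])},
        n_obs=len(data),
    )


def fit_humidity_factor(
    obs: Iterable[DegradationObservation],
) -> tuple[float, float]:
    """Isothermal humidity sweep: fit ln k = a + B rh, return (exp(a), B).

    The intercept absorbs the whole Arrhenius part at the (single) study
    temperature, so B is identified without any temperature variation.
    """
    data = _as_observations(obs)
    if len(np.unique([o.temperature for o in data])) != 1:
        raise ValueError(
            "fit_humidity_factor expects observations at a single "
            "temperature; use fit_degradation_arrhenius otherwise"
        )
    rh = np.array([o.rh for o in data])
    if len(np.unique(rh)) < 2:
        raise ValueError("need >= 2 distinct relative humidities")
    y = np.log([o.rate_constant for o in data])
    X = np.column_stack([np.ones_like(rh), rh])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.exp(beta[0])), float(beta[1])


# ---------------------------------------------------------------------------
# CSV readers

_TIME_UNITS = {"s": 1.0, "min": 60.0, "h": 3600.0, "day": 86400.0}


def read_isotherm_csv(path) -> list[IsothermPoint]:
    """Read isotherm points from CSV with columns ``rh, load_g_per_g``."""
    df = pd.read_csv(path)
    missing = {"rh", "load_g_per_g"} - set(df.columns)
    if missing:
        raise ValueError(f"isotherm CSV missing columns: {sorted(missing)}")
    return [IsothermPoint(float(r), float(x))
            for r, x in zip(df["rh"], df["load_g_per_g"])]


def read_uptake_csv(path, time_unit: str | None = None) -> list[UptakeCurve]:
    """Read uptake curves from CSV with columns ``rh, time*, normalized_load``.

    The time unit is declared either in the header (``time_s``, ``time_h``,
    ``time_min``, ``time_day``) or via the `time_unit` flag for a bare
    ``time`` column.
    """
    df = pd.read_csv(path)
    time_col, factor = None, None
    for col in df.columns:
        if col == "time":
            if time_unit is None:
                raise ValueError(
                    "bare 'time' column requires an explicit time_unit flag"
                )
            if time_unit not in _TIME_UNITS:
                raise ValueError(
                    f"unknown time unit {time_unit!r}; "
                    f"expected one of {sorted(_TIME_UNITS)}"
                )
            time_col, factor = col, _TIME_UNITS[time_unit]
        elif col.startswith("time_"):
            unit = col.removeprefix("time_")
            if unit not in _TIME_UNITS:
                raise ValueError(f"unknown time unit in column {col!r}")
            time_col, factor = col, _TIME_UNITS[unit]
    if time_col is None:
        raise ValueError("uptake CSV needs a time column (e.g. time_s)")
    missing = {"rh", "normalized_load"} - set(df.columns)
    if missing:
        raise ValueError(f"uptake CSV missing columns: {sorted(missing)}")
    curves = []
    for rh, grp in df.groupby("rh", sort=True):
        grp = grp.sort_values(time_col)
        samples = tuple(
            (float(t) * factor, float(x))
            for t, x in zip(grp[time_col], grp["normalized_load"])
        )
        curves.append(UptakeCurve(float(rh), samples))
    return curves


def read_degradation_csv(path) -> list[DegradationObservation]:
    """Read rate observations from CSV: ``temperature_K, rh, k_per_s``."""
    df = pd.read_csv(path)
    missing = {"temperature_K", "rh", "k_per_s"} - set(df.columns)
    if missing:
        raise ValueError(f"degradation CSV missing columns: {sorted(missing)}")
    return [
        DegradationObservation(float(t), float(r), float(k))
        for t, r, k in zip(df["temperature_K"], df["rh"], df["k_per_s"])
    ]
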