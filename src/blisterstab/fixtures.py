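"""Synthetic calibration data with known ground truth.

Every calibration routine in the package can be exercised without any
laboratory data: these generators draw isotherm points, normalized uptake
curves and degradation-rate grids from the package's own forward models,
optionally perturbed with multiplicative Gaussian noise of stated relative
standard deviation.  The generating ("truth") parameters are returned, and
written to a JSON sidecar when files are produced, so parameter-recovery
tests are self-contained.

Generation is strictly seed-deterministic: the same
:class:`FixtureSpec` produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .moist_air import R_GAS
from .rate_processes import GabIsotherm, gab_load

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "isotherm_points",
    "uptake_curve_samples",
    "degradation_grid",
]

_KINDS = ("isotherm", "uptake", "degradation-grid", "scenario")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset.

    ``kind`` is one of ``isotherm``, ``uptake``, ``degradation-grid`` or
    ``scenario``; ``truth`` the generating parameters (see the per-kind
    generator functions for keys); ``noise_sigma`` the relative standard
    deviation of the multiplicative Gaussian noise (0 for noiseless data);
    ``n_samples`` the number of points per series.  A seed is mandatory.
    """

    kind: str
    truth: dict
    seed: int
    noise_sigma: float = 0.0
    n_samples: int = 10

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if not isinstance(self.seed, int):
            raise ValueError("seed is mandatory and must be an int")
        object.__setattr__(self, "truth", dict(self.truth))


def _noisy(values: np.ndarray, sigma: float, rng: np.random.Generator):
    if sigma == 0.0:
        return values
    return values * (1.0 + sigma * rng.standard_normal(values.shape))


def isotherm_points(
    iso: GabIsotherm,
    n: int = 10,
    noise_sigma: float = 0.0,
    seed: int = 0,
    rh_range: tuple[float, float] = (0.05, 0.85),
) -> pd.DataFrame:
    """Equilibrium (rh, load) points from a GAB isotherm, optionally noisy."""
    rng = np.random.default_rng(seed)
    rh = np.linspace(*rh_range, n)
    load = np.array([gab_load(iso, r) for r in rh])
    return pd.DataFrame({"rh": rh, "load_g_per_g": _noisy(load, noise_sigma, rng)})


def uptake_curve_samples(
    rate_constants: dict[float, float],
    n: int = 12,
    noise_sigma: float = 0.0,
    seed: int = 0,
    t_max_factor: float = 5.0,
) -> pd.DataFrame:
    """Normalized uptake curves X/X_inf = 1 - exp(-k t) per humidity level.

    `rate_constants` maps rh level -> k (1/s); each curve is sampled at `n`
    times spanning `t_max_factor` relaxation times of its own k.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for rh in sorted(rate_constants):
        k = rate_constants[rh]
        t = np.linspace(0.0, t_max_factor / k, n + 1)[1:]  # skip t = 0
        y = -np.expm1(-k * t)
        frames.append(
            pd.DataFrame(
                {"rh": rh, "time_s": t,
                 "normalized_load": _noisy(y, noise_sigma, rng)}
            )
        )
    return pd.concat(frames, ignore_index=True)


def degradation_grid(
    pre_exponential: float,
    activation_energy: float,
    humidity_factor: float,
    temperatures=(313.0, 323.0, 333.0),
    rhs=(0.1, 0.4, 0.7),
    noise_sigma: float = 0.0,
    seed: int = 0,
    arrhenius_sign: int = -1,
) -> pd.DataFrame:
    """Degradation rate constants on a (T, rh) grid from the Arrhenius law."""
    rng = np.random.default_rng(seed)
    rows = []
    for T in temperatures:
        for rh in rhs:
            k = (
                pre_exponential
                * np.exp(arrhenius_sign * activation_energy / (R_GAS * T))
                * np.exp(humidity_factor * rh)
            )
            rows.append((T, rh, k))
    df = pd.DataFrame(rows, columns=["temperature_K", "rh", "k_per_s"])
    df["k_per_s"] = _noisy(df["k_per_s"].to_numpy(), noise_sigma, rng)
    return df


def generate_fixture(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Materialize a fixture as CSV (or YAML) plus a truth JSON sidecar.

    Returns the paths written, keyed ``"data"`` and ``"truth"``.  The same
    spec always produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{spec.kind}_seed{spec.seed}"
    truth_path = outdir / f"{stem}.truth.json"

    if spec.kind == "isotherm":
        iso = GabIsotherm(
            spec.truth["monolayer_load"], spec.truth["c_gab"], spec.truth["k_gab"]
        )
        df = isotherm_points(
            iso, n=spec.n_samples, noise_sigma=spec.noise_sigma, seed=spec.seed,
            rh_range=tuple(spec.truth.get("rh_range", (0.05, 0.85))),
        )
        data_path = outdir / f"{stem}.csv"
        df.to_csv(data_path, index=False)
    elif spec.kind == "uptake":
        df = uptake_curve_samples(
            {float(r): float(k) for r, k in spec.truth["rate_constants"].items()},
            n=spec.n_samples, noise_sigma=spec.noise_sigma, seed=spec.seed,
        )
        data_path = outdir / f"{stem}.csv"
        df.to_csv(data_path, index=False)
    elif spec.kind == "degradation-grid":
        df = degradation_grid(
            spec.truth["pre_exponential"],
            spec.truth["activation_energy"],
            spec.truth["humidity_factor"],
            temperatures=tuple(spec.truth.get("temperatures", (313.0, 323.0, 333.0))),
            rhs=tuple(spec.truth.get("rhs", (0.1, 0.4, 0.7))),
            noise_sigma=spec.noise_sigma,
            seed=spec.seed,
            arrhenius_sign=int(spec.truth.get("arrhenius_sign", -1)),
        )
        data_path = outdir / f"{stem}.csv"
        df.to_csv(data_path, index=False)
    elif spec.kind == "scenario":
        # Truth carries a fully-formed scenario document; written verbatim.
        import yaml

        data_path = outdir / f"{stem}.yaml"
        with open(data_path, "w") as fh:
            yaml.safe_dump(spec.truth, fh, sort_keys=False)
    else:  # pragma: no cover - guarded by FixtureSpec validation
        raise AssertionError(spec.kind)

    with open(truth_path, "w") as fh:
        json.dump(
            {"kind": spec.kind, "seed": spec.seed,
             "noise_model": {"type": "multiplicative-gaussian",
                             "sigma": spec.noise_sigma},
             "n_samples": spec.n_samples, "truth": spec.truth},
            fh, indent=2, sort_keys=True,
        )
    return {"data": data_path, "truth": truth_path}
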