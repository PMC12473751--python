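# Methods

## Model structure

A blister cavity is treated as a closed, isothermal, ideally mixed system
in which water occupies three compartments: the headspace vapor
(`m_vap`), the water sorbed to the tablet (`m_sor`) and the water already
consumed by hydrolytic degradation of the drug (`m_deg`). The total is
conserved up to what permeates through the foil:

```
m_vap + m_sor + m_deg = m_tot(0) + m_permeated(t)
```

Each compartment independently obeys first-order kinetics
`dm/dt = k (m_∞ − m)` toward its own limit, and the exact one-step
integral `m(t+Δt) = m_∞ − (m_∞ − m)·e^{−kΔt}` is used throughout; it is
unconditionally stable and never overshoots the limit. The limits are:

* permeation: the vapor mass in equilibrium with the *ambient* humidity
  (ideal gas law);
* sorption: the GAB equilibrium load at the *cavity* humidity times the
  tablet dry mass;
* degradation: the stoichiometric water demand of hydrolysing the entire
  drug load, `ν·M_w/M_d·m_drug` — a constant.

Because the sorption and degradation limits (and the degradation rate)
depend on the cavity humidity, which in turn follows from the balance,
the processes are genuinely coupled through the vapor phase. Degradation
is debited from the vapor compartment, not routed through the sorbed
water.

### Assumptions

Isothermal storage at constant ambient humidity; steady-state barrier
behavior of the foil (no film saturation transient); tablet sorption
properties and isotherm unchanged by accumulating degradation products;
rate constants constant within a time step and re-evaluated between
steps; ideal gas vapor; no moisture gradients inside the tablet or the
headspace. Time-varying (cycled) storage conditions and multi-cavity
coupling are out of scope.

## Numerics

### Dynamic time-step selection

`Δt = −ln(1 − σ)/k_fast`, where `k_fast` is the largest rate constant
among the *non-equilibrated* processes and σ (`step_criterion`, default
10⁻²) is the fraction of its remaining approach to equilibrium a single
step may traverse. A process is considered equilibrated when its gap to
the limit falls below 10⁻⁹ of its scale; when no finite-rate process is
active the step falls back to the output interval. The step never exceeds
the remaining horizon.

### Per-step fixed-point iteration

Within a step the solver iterates on the end-of-step cavity humidity φ:
sorption and degradation increments are evaluated at the current φ
estimate, permeation acts on the vapor mass after their drawdown (the
coupling that reduces the inward driving force), and the balance returns
an updated φ. Iteration stops when the relative change of *every*
compartment mass between successive iterates is at most ε
(`convergence_limit`, default 10⁻⁸); exceeding `max_iterations_per_step`
(default 10⁴) raises a diagnostic error with the failing time stamp.

Plain successive substitution diverges for realistic tablets: the
feedback gain of the loop is the ratio of the tablet's moisture buffer
slope to the headspace vapor capacity,

```
G = (dm_sor/dφ + dm_deg/dφ) · (1 − f_perm) / (M_w V p_sat / R T)
```

which is of order 10³ for the shipped case study (a 364 mg tablet buffers
a 0.41 mL headspace roughly 2000-fold). The φ update is therefore damped
with the analytic factor `1/(1 + G)`, with G recomputed each iteration
from the closed-form GAB slope. This is equivalent to a Newton step on
the linearized balance: convergence typically takes 2–7 iterations, and
the converged state is independent of the damping path. With weak
coupling (G → 0) the scheme reduces to plain substitution.

A computed negative vapor mass (degradation or sorption demanding more
water than the headspace holds within one step) is clamped to zero with a
`VaporDepletionWarning`; such moisture-starved regimes are outside the
model's validity and the warning count is reported in the run statistics.

### Fast-sorption shortcut

Tablet sorption rate constants measured on the DVS time scale can exceed
every other rate constant by many orders of magnitude (the shipped case
study uses 4.41 s⁻¹ against a permeation constant of ~7·10⁻⁵ s⁻¹).
Keying Δt to such a constant would force ~10¹⁰ steps over three years
while resolving a transient of no consequence. When the sorption rate
constant exceeds `fast_process_threshold` (default 10³) times **both**
the fastest other active rate constant **and** the recording rate
(1/output interval), the tablet is instead treated as instantaneously at
GAB equilibrium with the cavity within each step and Δt is keyed to the
next-fastest process. Both conditions matter: the second prevents the
shortcut from swallowing a sorption transient that the requested output
resolution could actually resolve. Shortcut use is counted in the run
statistics.

### Recording

States are recorded on a uniform output grid (plus the horizon endpoint)
by linear interpolation between the two bracketing integration steps.
Integration is never synchronized to the grid, so the recorded values at
common times are bit-identical across output intervals — the interval is
purely a recording parameter. Linear interpolation preserves the mass
balance exactly (it is a linear identity in the interpolated masses);
trajectories validate conservation at every recorded state to within ε.

### Verification

The engine is checked against three independent oracles: the closed-form
exponential for an empty blister (≤10⁻⁶ RH), a scalar root-finding oracle
for the sealed-system equilibrium water activity (≤10⁻⁶ relative), and a
stiff adaptive BDF integration of the three coupled rate equations at
rtol 10⁻¹⁰ on coupled scenarios (<10⁻³ RH everywhere). Residual sweeps
against fine-reference solutions decrease monotonically over
σ ∈ {10⁻¹, 10⁻², 10⁻³} and are non-increasing over
ε ∈ {10⁻⁴, 10⁻⁶, 10⁻⁸}, matching the expectation that σ ≈ 10⁻² and
ε = 10⁻⁸ are adequate defaults.

## Parameters

| Parameter | Symbol | Default | Unit | Notes |
|---|---|---|---|---|
| step criterion | σ | 10⁻² | – | fraction of equilibrium per step |
| convergence limit | ε | 10⁻⁸ | – | relative per-iteration mass change |
| max iterations/step | – | 10⁴ | – | diagnostic failure beyond |
| output interval | – | 86 400 | s | recording only |
| fast-process threshold | – | 10³ | – | sorption-shortcut ratio |
| stoichiometric factor | ν | 1 | – | moles water per mole drug |
| Arrhenius sign | – | −1 | – | exponent convention, see below |

All internal computation is SI (kg, m³, Pa, s, K); configuration files
carry explicit unit strings (mg, mL, kPa, g·m⁻²·day⁻¹, days, …) that are
converted on load, with no silent defaults.

### The degradation pre-exponential factor

The published cilazapril parameter set lists a pre-exponential factor of
5.43·10⁻¹⁸ s⁻¹ together with E_a = 1.71·10⁵ J mol⁻¹. No sign convention
for the Arrhenius exponent reconciles these magnitudes with
shelf-life-scale kinetics: with the standard negative exponent the rate
at 40 °C is ~10⁻⁴⁶ s⁻¹ (half-life ~10³⁷ years), with a positive exponent
~10¹¹ s⁻¹. Only reading the factor as 5.43·10⁺¹⁸ s⁻¹ under the negative
convention yields rates (~1.7·10⁻⁹ s⁻¹ at 40 °C / 70 % RH, half-life
~13 years) consistent with a drug that visibly degrades over a 3-year
shelf life. The package does not silently "fix" this: the sign and the
factor are both explicit inputs, `case_study.yaml` ships the printed
value verbatim and triggers a load-time plausibility warning (half-life
outside 10⁻⁶–10⁶ years), and `case_study_reinterpreted.yaml` ships the
reinterpreted value. The Arrhenius fitter likewise reports the fitted
1/T slope as-is; data generated under the positive convention surface as
a negative activation energy rather than being sign-flipped.

### Case-study WVTR values

The barrier parameters of the shipped material variants are
literature-typical class values for 100 µm thermoformed cavities at
40 °C (donor 90 % RH): PVC 3.0, PVC/PVdC 0.6 and PVC/Aclar
0.3 g m⁻² day⁻¹ — film datasheet values adjusted upward for the thinning
that thermoforming produces in the cavity dome. With these inputs the
predicted two-year drug-content advantage of the PVC/Aclar blister over
an unpacked tablet is ≈2.7 percentage points, and the plain-PVC
prediction tracks the unpacked curve closely.

### Sorption kinetics

A sorption rate constant of 4.41 s⁻¹ (as published for the case-study
tablet) implies equilibration within seconds, which conflicts with the
hours-scale kinetics typical of DVS experiments; it is nevertheless used
verbatim, and the fast-sorption shortcut makes the simulation insensitive
to its exact magnitude once it is far above every other rate. Humidity-
dependent sorption kinetics are supported as a tabulated (rh, k) map with
linear interpolation.

## Calibration fitters

* **GAB** (`fit_gab`): bounded trust-region least squares with five
  deterministic starting guesses; bounds keep 0 < K < 1 so the isotherm
  stays finite on [0, 1]. Standard errors from the Gauss–Newton
  covariance. Exact on noiseless data. Under 1 % multiplicative noise on
  a 10-point isotherm, w_m and K are recovered to ~3 %, while C — the
  parameter controlling the low-humidity knee — is weakly identified and
  can deviate beyond 5 % for unfavorable noise draws; the fixed-seed
  fixtures used in the tests recover all three within 5 %.
* **Sorption rate** (`fit_sorption_rate`): per-curve single-exponential
  fits (optimized in log k for positivity); a pooled inverse-variance
  mean is returned only when all per-humidity 95 % confidence intervals
  overlap pairwise, otherwise the per-humidity table is the result and
  the pooled value is flagged inconsistent. The overlap rule is this
  package's operationalization of "one rate constant for all humidity
  levels when the data allow it".
* **Humidity-corrected Arrhenius** (`fit_degradation_arrhenius`): OLS of
  ln k on (1/T, rh) — the model is linear in these coordinates, so
  noiseless grids are recovered to machine precision; returns R² and
  standard errors. A single-temperature humidity sweep is handled by
  `fit_humidity_factor`, whose intercept absorbs the Arrhenius part.

## Synthetic data

The fixture generators draw from the package's own forward models:
isotherm points on a uniform humidity grid (default 10 points over
0.05–0.85), normalized uptake curves over five relaxation times, and
(T, rh) rate grids (default 3×3 over 313–333 K × 0.1–0.7). Noise is
multiplicative Gaussian with stated relative σ, seeded and byte-
reproducible. They emulate clean, equilibrated laboratory data; they do
not emulate sorption/desorption hysteresis, instrument drift, baseline
artifacts or heteroscedastic assay error, so passing recovery tests
demonstrates correctness of the estimators, not robustness to every
real-data pathology.

## Known limitations

* Isothermal, constant-ambient storage only; no ICH cycling.
* Single cavity, single tablet; no tablet-internal diffusion gradients.
* Degradation is strictly water-consuming first-order hydrolysis; the
  water-free degradation pathways that some drugs exhibit are not
  modeled, and degradation never stops solely because vapor is depleted —
  the vapor-clamp warning marks such runs as outside validity.
* Only the GAB isotherm family ships; alternative isotherms would slot in
  at the `TabletSpec.isotherm` boundary but are not implemented.
* The degradation rate reads the cavity humidity by default; an optional
  mode (`degradation_rh_mode: tablet`) uses the tablet's instantaneous
  water activity via the inverse isotherm instead, for formulations where
  the microclimate inside the tablet governs water availability.
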