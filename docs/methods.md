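# Methods

## Model

`emotransfer` implements a one-way transfer system between the
cumulative information amounts of online emotions. Each of *n* source
emotions follows logistic growth with an extra outflow term, and a
single target emotion receives part of that outflow:

```
dx_i/dt = r_i x_i (1 − x_i/K_i − b_i x_i/K_i),   x_i(0) = x_i0
dy/dt   = r y (1 − y/K + Σ_i a_i b_i x_i/K_i),   y(0)  = y_0
```

Assumptions: amounts are cumulative, continuous and strictly positive;
transfer is unidirectional (sources never receive), sources are
mutually independent, and the conversion proportion `b_i` and transfer
coefficient `a_i` are constants in the open interval (0, 1). Because
`x_i` and `y` are non-zero and monotone under these assumptions, the
system has exactly one non-zero fixed point,

```
x_i* = K_i/(1+b_i),       y* = K (1 + Σ_i a_i b_i/(1+b_i)),
```

which the flow approaches from any initial state strictly between 0 and
the fixed-point coordinates. Sources are *compressed* below their
capacity (division by 1+b_i); the target is *inflated* above its own.
Stability is checked numerically, not by eigenvalue analysis.

Time is dimensionless: 1 unit = one sampling interval of the observed
series (a day, for daily platform counts), and all rates are per
interval.

### Parameters

| parameter | meaning | domain | typical default |
|---|---|---|---|
| `r_i`, `r` | intrinsic growth rate per interval | > 0 | fixture values |
| `K_i`, `K` | capacity of the cumulative amount | > 0 | fixture values |
| `b_i` | conversion proportion (guiding strength) | (0, 1) | — |
| `a_i` | transfer coefficient (guiding efficiency) | (0, 1) | — |

The open-interval constraint on `a_i`, `b_i` is enforced strictly;
`unchecked=True` on a source spec relaxes it for exploratory work only
(negative coefficients, which would describe reverse transfer, are out
of scope).

## Numerics

* **Integration.** Adaptive RK45 (`scipy.integrate.solve_ivp`) with
  relative tolerance 1e-10 and absolute tolerance 1e-12. "Integrate to
  equilibrium" (`equilibrate`) means integrating until the maximum
  derivative scaled by the largest state component falls below 1e-10
  (located by a terminal event), with a hard horizon cap of 2000
  intervals; half a tolerance of slack absorbs the event root-finding
  error. Tolerances much below the integrator's own error floor
  (roughly `rtol × state scale`) are not attainable and raise an error.
* **Fixed-step Euler** (`method="euler"`) exists because a unit Euler
  step is exactly the difference recursion the estimator assumes; it is
  used for estimator oracles and overlay trajectories, not for
  production simulation.
* **Rounding.** Tables and CLI summaries display 3 decimals; CSV output
  serializes 12 significant digits; full precision is kept internally.
* A simulated sweep can differ from the closed form in the third
  decimal at finite horizons (e.g. a source equilibrium of 421.053 may
  be quoted as 421.00x after a short run); both the simulated and the
  closed-form values are therefore reported in sweep tables.

## Estimation

At unit steps the model linearizes to the difference equations

```
ΔX(k) = r x − (r(1+b)/K) x²
ΔY(k) = r y − (r/K) y² + r Σ_i (a_i b_i/K_i) x_i y
```

fitted by ordinary least squares **without intercept** (the model has
none); an intercept can be added only as a misfit diagnostic.
Alignment convention: `ΔX(k) = x(k) − x(k−1)` is regressed on the
*lagged* state `x(k−1)`, `x²(k−1)` — the forward-Euler convention, the
same recursion the difference-mode generator uses, so noise-free
recursion data is recovered to machine precision. Fitting ODE-sampled
data instead incurs a discretization bias that shrinks with the
sampling step (verified in tests at two step sizes).

**Identifiability.** The source equation identifies only `r` and the
effective capacity `κ = K/(1+b)`; the target equation identifies `r`,
`K` and the composites `ψ_i = a_i b_i/K_i`. No regression output can
split κ into (K, b) or ψ into a. The estimator therefore returns
composites by default and resolves full parameters only given an
explicit per-source **anchor**: a known `K_i` (`b = K/κ − 1`,
`a = ψK/b`), a known `b_i`, or a pre-guidance window of the series on
which a plain logistic fit (b = 0) supplies `K_i`. Anchors implying
coefficients outside (0, 1) raise a domain error naming the offending
composite. Any admissible anchor yields identical observable dynamics
— verified in tests by simulating two resolutions.

**Diagnostics.** For the no-intercept model, R² is the uncentered
coefficient of determination, VIFs come from uncentered no-intercept
auxiliary regressions, and the overall F is `(ESS/p)/(SS_res/(m−p))`
with ESS the sum of squared fitted values. These conventions are
stamped into every diagnostics output, because printed diagnostic
values from other workflows are not comparable without their data and
conventions.

Input series must be cumulative; raw daily counts are cumulated after
validating non-negative increments, and decreasing "cumulative" input
is rejected with row/column coordinates rather than silently clipped.

## Scenario lab

Sweeps follow the two controlled designs (coefficients trading off as
`a_2 = 1 − a_1` with b fixed, and vice versa) on the inclusive 9-point
grid 0.1..0.9. In the conversion-controlled design with `a_1 + a_2 = 1`
the closed-form `y*` depends only on `a_1 b + a_2 b = b` and is exactly
constant across rows; any spread in a simulated sweep is a
finite-horizon artifact (asserted < 0.05 in tests).

Scenario selection integrates the target trajectory under the
estimated `(a_2, b_2)` and under the scenario-mapped pair, then takes
the Euclidean distance on a time grid defaulting to the observed
sampling indices 0..m (m = 11 mirrors a 12-day collection window).
Absolute distances scale with the grid and are not comparable across
conventions; only the rank order is asserted. "Unconstrained" means
the estimated coefficients (iteration index zero of the policy search);
a `no-transfer` baseline (a_i → 0) is available behind a flag as the
alternative reading. Ranking ties break on ascending scenario id.

## Strategy optimization

The equilibrium surface over `(a_1, b_1)` is fitted with the six
quadratic monomials by least squares on the 81-point scenario grid,
using closed-form equilibria by default (deterministic; a flag switches
to finite-horizon simulated values). Gradient ascent uses a fixed step
γ (default 1e-7, matching the magnitude of surfaces whose values are in
the 10⁵–10⁶ range; sensible γ scales inversely with surface curvature,
and a step below `1/max|curvature|` keeps the path monotone). The path
stops before leaving the closed box `[0.01, 0.99]²` (parameters are
proportions), on update norms below 1e-12, or at 100 iterations; the
termination reason is always reported. The n = 0 row of a policy path
has zero relative changes by definition.

## Synthetic data

The generator emulates per-category cumulative counts from a platform
monitoring feed. `difference` mode runs the exact unit-step recursion
(the estimator's model class — exists precisely to separate regression
error from discretization error); `ode` mode samples the continuous
flow at unit steps. Observation noise multiplies per-step increments by
independent log-normal factors with unit mean (default σ = 0.05),
preserving positivity and monotone cumulativity; the model itself says
nothing about noise, so this is a deliberately mild choice. Parameter
sets whose recursion would overshoot into decreasing values (effective
per-step growth ≳ 1 near saturation) raise a step-size error advising
`ode` mode. Default horizon: 12 steps, the length of a typical
two-week event window.

What synthetic tests do *not* show: real platform series include
classifier noise, trend breaks when guidance begins, weekday effects
and non-logistic early growth; passing round-trip tests demonstrates
correctness of the estimator on its own model class, not robustness to
those features.

### Fixtures

`table2` is the simulation-study parameter set (negative: x0=80,
r=0.7, K=800; neutral: x0=40, r=2, K=400; positive: y0=20, r=1, K=300)
with coefficients left unset for sweeps. `table6` is the published
case-study regression result; its source data was never deposited, so
the values are constants, and the unpublished initial values are set to
5% of each capacity (a synthetic choice that equilibrium quantities do
not depend on). With `table6`'s growth rates (≈1.1–1.6) the unit-step
recursion overshoots, and its tiny ψ₁ ≈ 2.8×10⁻⁹ is below the
discretization bias of unit-step fitting — so the fixture supports
simulation, scenario ranking and optimization, not estimator
round-trips.

## Known limitations

* One-way n→1 transfer only; no reverse or many-to-many flows, and no
  negative coefficients.
* The difference regression is the linearized scheme, not nonlinear
  least squares on the ODE; no uncertainty beyond standard regression
  outputs.
* Policy-path iterate tables depend jointly on the fitted surface and
  γ; only their structural properties (monotone ŷ, zero first-row
  relative changes, termination reasons) are guaranteed.
* Scenario-distance magnitudes depend on the time grid; treat them as
  ordinal.
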