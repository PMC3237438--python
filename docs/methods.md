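# Methods

## Model

Seasonal biomass accumulation is treated as the output of three coupled
unit processes, all analytic:

1. **Energy driving function.** Incident solar energy over the season is
   taken as Gaussian in calendar time with mean `mu` (wk since Jan. 1) and
   spread `sigma_sqrt2` = √2·σ (wk). Its cumulative integral enters through
   the error function.
2. **Partitioning.** New biomass divides between light-gathering (leaf) and
   structural (stalk) tissue; the dimensionless partition coefficient `k`
   adds a Gaussian term `(k/√π)(exp(−x_i²) − exp(−x²))` to the erf
   integral.
3. **Aging.** A linear aging rate `c` (1/wk) acts as a time shift: the
   dimensionless time is `x = (t − mu)/sigma_sqrt2 + c·sigma_sqrt2/2`, so
   the effective origin moves earlier by `c·sigma_sqrt2²/2` weeks (6.4 wk
   for the default set: the zero of x moves from week 26.0 to week 19.6).

Growth begins at the dimensionless initiation time `x_i`
(calendar `t_i = mu + sigma_sqrt2·(x_i − c·sigma_sqrt2/2)`), where the
growth quantifier Q is exactly zero; before `t_i`, Q is reported as 0.
Q is strictly increasing on [x_i, ∞) — dQ/dx = (2/√π)e^(−x²)(1 + k(x −
x_i)) > 0 — and saturates at
`Q(∞) = (1 − k·x_i)(1 − erf x_i) + (k/√π)exp(−x_i²)`.

Yield is linear in the quantifier, `Ŷ = b + A·Q`; cumulative uptake of
each mineral element follows the rectangular hyperbola
`N_u = N_um·Y/(K_y + Y)` and concentration is its ratio form
`N_c = N_um/(K_y + Y)`, strictly decreasing in Y. The model asserts
equilibrium coupling of uptake to biomass, not root-zone mechanism:
photosynthesis is the rate-limiting process, and the monotone decline of
concentration after initiation reflects the shift from leafy to structural
tissue.

## Parameters

| parameter | meaning | unit | default (`florence-1982`) |
|---|---|---|---|
| `mu` | mean of the solar-energy distribution | wk | 26.0 |
| `sigma_sqrt2` | spread √2·σ of that distribution | wk | 8.0 |
| `c` | aging coefficient | 1/wk | 0.2 |
| `k` | light-gathering vs structural partition | — | 5.0 |
| `x_i` | dimensionless initiation time | — | 0.0 |
| `A`, `b` | yield factor and intercept | Mg/ha | fitted |
| `N_um` | potential maximum uptake | kg/ha | fitted |
| `K_y` | biomass at half-maximal uptake | Mg/ha | fitted |

`mu`, `sigma_sqrt2`, `c`, `k` and `x_i` are treated as a named, versioned
input set, not fitted here: they come from prior cross-study analysis, and
this package provides no recipe to estimate them from radiation records.
`A`, `b`, `N_um`, `K_y` are estimated from data by OLS.

## Estimation

Both calibrations are linear least squares:

- **Yield factor:** OLS of Y on Q. The default includes an intercept —
  the observed series has Y = 0.406 Mg/ha already at Q = 0, so a free
  intercept is needed to represent the fit actually supported by the data —
  with a `with_intercept=False` option for the strict proportional form
  (closed form ΣQY/ΣQ²). Duplicated rows count twice, as in any OLS.
- **Phase relation:** OLS of Y/N_u on Y; `N_um = 1/slope`,
  `K_y = intercept/slope`. The linearization is exact on noiseless data
  (recovery to machine precision), which the property tests exploit. A
  nonlinear least-squares refit of the hyperbola (scipy `curve_fit`,
  initialized from the linearized estimates) is provided for comparison
  only; it weights large-biomass rows more and sits below the linearized
  `N_um` on the corn data (262 vs 273 kg/ha for N). The linearized fit is
  canonical because it is the form the published coefficients derive from.
  Rows with zero uptake are dropped with a warning; a negative fitted slope
  or intercept raises "phase relation not supported by data".
- **Initiation scan:** total potential `Q(∞)` is evaluated over a grid of
  candidate `x_i ≥ 0`. The domain is restricted to non-negative `x_i`
  because the asymptote formula grows without bound as `x_i → −∞`; on the
  admissible domain `Q(∞)` is non-increasing, so `x_i = 0` is the maximal
  choice ("initiate as soon as the shifted energy integral starts").

The efficiency ratio `N_um / applied` is reported to 2 d.p.; values near 1
mean the crop could express essentially all of the applied element.

## Synthetic data generator

`generate(SynthConfig)` emulates a season of destructive samplings in the
layout of the corn fixture: 6 default sampling times (weeks 19.6–29.5),
truth `Y = b + A·Q(t)` and hyperbolic uptake, then observational noise.
The default noise model is multiplicative lognormal, mean-preserving, with
a configurable coefficient of variation applied independently to Y and to
each element's uptake — field biomass errors scale with magnitude.  An
additive-Gaussian alternative (sd = cv·truth) and a noiseless mode exist.
No error model is inherited from the source study; this one is declared.
Concentration columns are always recomputed as uptake/Y from the noised
values, never independently perturbed.  Seeding is a single integer;
per-variable substreams are derived from (seed, column label) so adding an
element never perturbs the draws of the others.  Sampling rows whose true
yield is non-positive (pre-initiation with b ≤ 0) are emitted with uptake 0
and a `pre_initiation` flag.

What the generator does **not** emulate: weather-driven year effects,
serially correlated measurement error, plot-to-plot spatial variance, or
measured reversals of cumulative uptake (the corn potassium column reverses
298 → 267 → 293 kg/ha; the fixture keeps that verbatim, the generator only
produces such reversals incidentally through noise).  Passing
recovery tests therefore demonstrates estimator correctness and noise
sensitivity under this idealized observation model, not robustness to real
field pathologies.

## Numerical choices

- erf via `scipy.special.erf`, validated in the tests against direct
  quadrature of (2/√π)e^(−u²) to 1e−6.
- The trajectory is pointwise closed-form evaluation on a time grid
  (default t ∈ [15, 32] wk, dt = 0.1); no ODE solver, hence refining dt
  changes nothing at shared grid points.
- `quantifier_table` clamps Q to exactly 0 within 1e−12 above `x_i`: a
  calendar time equal to the computed initiation time lands within a few
  ulp of `x_i`, where Q < 1e−11 anyway.
- Strict-monotonicity checks run on x ∈ [x_i, x_i + 4]; beyond x ≈ 5 the
  analytic slope of Q falls below one ulp of its magnitude and float
  increments can be 0.
- Comparison against the published corn tables uses ±0.0005 for x, erf x
  and exp(−x²) (printed to 3–4 d.p.) and ±0.001 for Q (rounded values).

## Known data caveats in the shipped fixture

The corn tables are shipped verbatim.  Two internal inconsistencies are
documented rather than repaired: the correlation table's t = 21.0 row
prints erf 0.1999 for x = 0.175 (erf(0.175) = 0.1955), so its printed
Q = 0.285 is not reproducible by a correct evaluation (the self-consistent
value is 0.281); and the P/K concentration cells at t = 26.8 disagree with
uptake/Y beyond the rounding of whole-kg uptakes (e.g. 267/18.8 = 14.2 vs
the printed 12.5 g/kg) — the reader emits a warning for such cells.  The
nitrogen concentration column is consistent to 0.1 g/kg throughout.

## Problem sizes

The recovery study uses 120 seeds per noise level at cv ∈ {0.01, 0.05,
0.10} with single-element (N) synthetic seasons of 6 samplings, and the
noise-calibration check uses 500 replicates; these sizes give stable
medians while keeping the whole suite fast.

## Limitations

- `mu`, `sigma_sqrt2`, `c`, `k` are inputs; no joint estimation from yield
  data is attempted, so mis-specified energy parameters propagate silently
  into A.
- The phase relation summarizes equilibrium coupling; it cannot represent
  uptake reversals (leaching, leaf drop) such as the potassium column shows.
- The intercept b is a fitting device, not biology: the model proper has
  Y = A·Q, and b ≈ 0.3 Mg/ha absorbs the pre-initiation biomass of the
  first sampling.
- Calendar time is decimal weeks since Jan. 1, northern hemisphere; no
  date parsing is provided.
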