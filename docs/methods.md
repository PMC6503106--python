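# Methods

## Model

The package couples three standard pieces of microbial growth theory:

1. **Exponential growth calculus.** Between two density readings the
   specific growth rate is `mu = ln(x2/x1)/(t2 - t1)`; its inverse,
   `N0 = N(t) * exp(-mu t)`, back-calculates an initial density from an
   end-point count. These exact inverses are the backbone of the biofilm
   inference.

2. **Monod kinetics.** `mu(S) = mu_max * S / (Ks + S)`, with `S` in
   fractions of full-strength medium (1.0 = undiluted). Using a fraction of
   a complex medium as "the" substrate treats the medium as a single
   limiting resource; that is an approximation the estimation procedure
   inherits — the fitted `Ks` is a property of the medium dilution series,
   not of any one chemical species.

3. **Chemostat balance (Novick–Szilard).** At steady state `mu(S_bar) = D`
   gives `S_bar = Ks D/(mu_max - D)` independent of inflow `Sr` and yield
   `Y`; then `X_bar = Y (Sr - S_bar)`, `P = D X_bar`, and washout occurs at
   `D >= D_crit = mu(Sr)`. The boundary point `D = D_crit` is classified as
   washout (the positive branch exists only strictly below it). Production
   is maximised at `D_opt = mu_max (1 - sqrt(Ks/(Ks + Sr)))`, which the test
   suite cross-checks against a brute-force grid search.

The ODE module integrates `dX/dt = (mu(S) - D) X`,
`dS/dt = D (Sr - S) - mu(S) X / Y`. The substrate equation is the standard
well-mixed mass balance consistent with the definition of `Y`. No lag or
delay terms: the Monod response is instantaneous. Biofilm biomass is *not*
fed back into the liquid-phase budget; the attached population is treated
as a passive consumer of the ambient `S_bar`, which is the model's central
simplification.

### Biofilm inference

Slide-exposure assays measure only an end-point surface density. The
inference assumes (a) the sparsest assay — by default the lowest dilution
rate, where cells remain a dispersed monolayer — grew at the plankton rate
`mu = D` throughout the exposure, so its initial attached density `N0` can
be back-calculated; and (b) that `N0`, interpreted as the attachment supply
over the exposure window, is common to the other assays, whose growth rates
then follow as `ln(N_final/N0)/t`. The reference assay's inferred rate
equals its dilution rate by construction (an identity the tests assert).
"Initial density" conflates attachment flux with a true inoculum; the
arithmetic is retained as-is, and the caveat matters when comparing assays
with very different production of planktonic cells. Viability fractions are
reported but never enter rate estimates: the total (nucleic-acid-stained)
count is the modelled quantity.

### Flow-domain classification

Dilution rate enhances biofilm growth only while it is commensurate with
achievable microbial growth rates; the slow/intermediate boundary is set at
4 h⁻¹ (about the fastest recorded prokaryotic growth rate). Far beyond it,
only shear stress matters: ≤ 0.04 Pa is buildup-permissive, ≥ 1 Pa
destructive. The fast-flow boundary is taken one order of magnitude above
the slow bound (40 h⁻¹), a convention — reported flow-cell systems run at
19–260 h⁻¹ and all classify as fast; both boundaries are inclusive to
"intermediate" and configurable.

## Parameters and defaults

| parameter | default | units | note |
|---|---|---|---|
| `mu_max` | 1.07 | h⁻¹ | reference *E. faecalis*/TSB fit |
| `Ks` | 0.019 | medium fraction | reference fit |
| `Y` | 0.4 | – | supplied constant, never estimated (no data to do so) |
| `Sr` | 4.0 / 0.06 | medium fraction | case1 (rich) / case2 (restricted bench condition) |
| fit window | 3 points | – | two 30-min intervals; see bias note below |
| ODE rtol | 1e-8 | – | LSODA; near-washout runs are stiff |
| `noise_cv` | 0.05 | – | OD read noise (synthetic) |
| `stack_cv` | 0.2 | – | between-stack count scatter (synthetic) |
| inoculum | 1e-4 | substrate-equivalent a.u. | see below |
| exposure | 24 | h | slide exposure |

## Estimation choices

**Double-reciprocal fit.** `(mu_max, Ks)` come from unweighted OLS on
`(1/S, 1/mu)`; intercept = `1/mu_max`, slope = `Ks/mu_max`. The reciprocal
transform over-weights slow-growth points and is not the most accurate
estimator; `method="nls"` refits the Monod curve directly by nonlinear
least squares seeded from the reciprocal estimate. Points with `S = 0` or
`mu = 0` are excluded (undefined reciprocals) with a logged count. On exact
curve points both methods invert the rate law to machine precision.
Monte-Carlo calibration at 5% multiplicative read noise with 20 replicates
per concentration puts the reciprocal estimates within 5% (`mu_max`) and
15% (`Ks`) of truth across seeds, with worst-case errors well inside those
bounds.

**Sliding-window max rate and its bias.** The "highest growth rate" of a
batch curve is the maximum OLS slope of `ln(OD)` vs time over a sliding
window. On noiseless curves the 3-point default tracks `mu(S0)` within 2%
provided the inoculum is small enough that the first window lies in the
early exponential phase. Under read noise, however, the maximum of many
noisy slopes is an order statistic and biases the rate *upward* — at 5%
noise and 30-min sampling, a 3-point window inflates the fitted `mu_max` by
~7%, while a 7-point (3 h) window keeps the bias near 1% without leaving
the exponential phase. Recommendation: window 3 for clean curves, ≥ 7 for
noisy ones; the noisy-pipeline tests use 7.

**Inoculum.** Batch curves start at `X0 = 1e-4` substrate-equivalent units.
At the most dilute medium (1/128), the final biomass is only `Y/128 ≈ 0.003`;
a larger inoculum (e.g. 1e-3) would consume >10% of the substrate within
the first sampling window, so no window would see the initial rate `mu(S0)`.
1e-4 keeps first-window substrate depletion near 1% at every dilution while
remaining a realistic overnight-culture transfer.

## Synthetic data

Generators are pure functions of (spec, seed): batch curves are the D = 0
limit of the chemostat ODEs sampled at 30-min intervals over the dilution
series (halving steps, 1/32 omitted, matching the reference design); biofilm
assays draw per-stack lognormal counts (7, 7, 4 stacks by default) around
`N0 exp(mu t)`; chemostat series perturb a simulated trajectory. All noise
is multiplicative lognormal — positive-valued proxies with
signal-proportional scatter — mean-corrected so noisy values are unbiased
around the noiseless curve, with CV 0.05 (OD) and 0.2 (stack counts) by
default; no noise magnitudes were available to match, so these are field-
plausible choices. What the generators deliberately omit: lag and death
phases, OD-to-biomass calibration error, segmentation artefacts in image
counts, and any feedback of wall growth on the liquid phase. Passing
round-trip tests therefore demonstrates internal consistency of the
inference chain, not robustness to those real-data effects.

## Numerical choices

- Steady states and production shares are closed-form; report-layer rounding
  is to table precision (2 significant figures, ties away from zero) while
  all internal computation is full precision.
- ODE integration: LSODA, rtol 1e-8, atol 1e-12; tiny negative excursions
  are clamped to zero with a logged warning. Convergence detection measures
  deviations relative to the closed-form steady values, falling back to the
  initial value as scale when the target is zero (washout).
- Test problem sizes: convergence grids of ~6 (D, X0, S0) combinations,
  production grid at step 1e-4, 50-seed fit and 200-seed biofilm Monte
  Carlos — sizes at which the calibrated tolerances are stable.

## Known limitations

- The Case 2 production share at the highest bench rate is hypersensitive
  to `mu_max` near washout: with the stored constants it evaluates to ≈4%
  of the maximum, and a ±0.2% change in `mu_max` moves it by whole
  percentage points. Quantities that depend on `Sr - S_bar` near `D_crit`
  should be treated as order-of-magnitude.
- Single limiting resource, fixed yield, no inhibition or variable-yield
  (Droop) kinetics, single species.
- The biofilm model is zero-dimensional exponential accumulation; it ignores
  diffusion limitation in multilayer films, detachment/sloughing, and
  attachment proportional to planktonic production — all of which matter at
  high surface densities.
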