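# chemofilm

Growth kinetics of suspended and surface-attached microbes under flow:
Monod parameter estimation from batch growth curves, closed-form chemostat
steady states and washout, time-domain chemostat simulation, and inference
of biofilm accumulation rates from timed surface cell counts.

## The problem

In a chemostat — a continuously fed, well-mixed culture vessel — the
suspended (planktonic) population must grow exactly as fast as it is washed
out, so at steady state its specific growth rate equals the dilution rate
*D*. With Monod kinetics

```
mu(S) = mu_max * S / (Ks + S)
```

this pins the residual substrate concentration at

```
S_bar(D) = Ks * D / (mu_max - D)
```

independently of the inflow concentration `Sr` and of the biomass itself.
The steady-state biomass follows from the yield coefficient,
`X_bar = Y * (Sr - S_bar)`, the harvestable production is `P = D * X_bar`,
and a positive steady state exists only below the critical dilution rate
`D_crit = mu(Sr)`.

The consequence for biofilms: surface-attached cells feed on `S_bar(D)` but
are not washed out, so faster dilution — which *reduces* planktonic biomass —
*raises* the substrate available to the biofilm and hence its growth rate.
This package implements that whole chain: estimating `(mu_max, Ks)` from a
batch dilution series via the double-reciprocal line (with a nonlinear
refit option), predicting `S_bar`, `X_bar`, `P` and washout across dilution
rates, verifying the closed forms against the chemostat ODEs

```
dX/dt = mu(S) X - D X
dS/dt = D (Sr - S) - mu(S) X / Y
```

and back-calculating biofilm kinetics from end-point cell counts,
`N(t) = N0 * exp(mu t)`. It also classifies flow regimes (dilution-rate
driven below ~4 h⁻¹, shear-stress driven far above it). Substrate
concentrations are expressed as fractions of full-strength medium, so `Ks`
and `Sr` share that unit.

It ships with a reference scenario — *Enterococcus faecalis* ATCC 29212 on
Trypticase Soy Broth, `mu_max = 1.07 h⁻¹`, `Ks = 0.019`, `Y = 0.4`, with a
nutrient-restricted inflow `Sr = 0.06` run at `D = 0.09, 0.28, 0.81 h⁻¹` —
and synthetic-data generators with known ground truth for every inference
stage.

## Worked example

```python
import chemofilm as cf
from chemofilm.report import steady_substrate_table, assay_summary_table

print(steady_substrate_table().to_string(index=False))
print(assay_summary_table().round(4).to_string(index=False))
```

```
   D    S_bar  S_bar_over_Ks  S_bar_rounded  S_bar_over_Ks_rounded
0.09 0.001745       0.091837         0.0017                  0.092
0.28 0.006734       0.354430         0.0067                  0.350
0.81 0.059192       3.115385         0.0590                  3.100

   D  doubling_time_h  pct_mu_max  cells_per_cm2  initial_density_per_cm2  mu_biofilm  nonviable_pct  pct_highest_P
0.09           7.7016      8.4112      3780000.0              435928.9575      0.0900           72.2           35.0
0.28           2.4755     26.1682     55400000.0                      NaN      0.2019            0.8          100.0
0.81           0.8557     75.7009     79400000.0                      NaN      0.2169            4.3            4.0
```

Reading the tables: residual substrate rises 35-fold (0.0017 → 0.059) over a
9-fold increase in dilution rate, reaching 3.1×Ks just below the washout
bound `D_crit = mu(0.06) = 0.81 h⁻¹`. The biofilm assays show the payoff:
the measured one-day surface density grows from 3.78×10⁶ to 7.94×10⁷
cells cm⁻² (21×) between the slowest and fastest rate. Anchoring on the
sparse-monolayer assay at `D = 0.09` — assumed to grow at the plankton rate,
giving an initial attached density of 4.36×10⁵ cells cm⁻² — the inferred
biofilm growth rates are 0.09, 0.20 and 0.22 h⁻¹, a 2.4× increase, even
though planktonic *production* peaks at the middle rate (100% at
`D = 0.28`).

The same computations are scriptable from the shell:

```sh
chemofilm report --out out/
chemofilm critical-d --config case2.yaml           # 0.8126582278481014
chemofilm sweep --config case2.yaml --d-max 0.81 --step 0.01 --out sweep.csv
chemofilm classify --d 0.81 --shear-pa 0.02        # {"domain": "slow", ...}
```

where `case2.yaml` is simply `case: case2` (optionally with `D: [...]`).

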