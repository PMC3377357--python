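# bcmpbpk

Physiologically based pharmacokinetic (PBPK) analysis of bromochloromethane
(BCM, CH₂BrCl) closed-chamber gas-uptake kinetics in rats.

BCM is a volatile water-disinfection by-product whose *in vivo* metabolism
shows a saturable component superimposed on a linear one. Two mechanisms can
produce that shape, and closed-chamber (vapor-uptake) data alone cannot
separate them:

* **two-pathway** — CYP2E1 oxidation with Michaelis–Menten kinetics plus a
  first-order glutathione-S-transferase (GST) conjugation pathway:

  `Met_liv = 0.948 · ( Vmax·C_liv/(Km + C_liv) + kGST·C_liv·V_liv )`

* **two-binding-site** — a single CYP2E1 enzyme with an active site and an
  effector site (atypical kinetics), asymptotically linear at high substrate:

  `Met_liv = 0.948 · ( Vmax1·C_liv + CL2·C_liv² ) / (Km1 + C_liv)`

with the kidney carrying the complementary 5.2% share of either law. The
package couples these rate laws to a seven-compartment flow-limited PBPK
model of an adult F344 rat (lung and blood algebraic at steady state;
adipose, rapidly perfused, slowly perfused, liver and kidney as ODE
compartments) breathing in a sealed 9 L chamber with three animals and a
0.025/hr leak. It then:

1. **simulates** chamber and tissue time courses after a bolus (stiff LSODA
   integration, mass balance closed to ~1e-15 relative);
2. **generates** synthetic five-series uptake designs (200–4000 ppm) with
   multiplicative lognormal measurement noise, standing in for the historical
   digitized curves, which were never deposited;
3. **estimates** the three metabolic parameters of either hypothesis by
   Nelder–Mead minimisation of a natural-log least-squares cost over all
   series jointly, with positivity enforced by a log-parameter transform;
4. **quantifies identifiability** via normalized local sensitivity
   coefficients `S(t) = (p/y) ∂y/∂p` for chamber air and liver
   concentration, 3-D sensitivity surfaces over a parameter-variability
   range, and the conditioning of the sensitivity time-course matrix.

It is aimed at toxicokinetic modellers who want a reproducible, testable
re-implementation of this analysis — every stage works from synthetic data
generated by the model itself, so the full pipeline runs without any
external download.

## Worked example

Simulate the canonical 500 ppm experiment under the two-pathway hypothesis
with the package's default parameter set (Vmax = 3.8 mg/hr, Km = 0.35 mg/L,
kGST = 4.7/hr):

```python
import numpy as np
from bcmpbpk import ClosedChamberConfig, simulate, mass_balance_residual

cfg = ClosedChamberConfig(c0_ppm=500.0)          # two-pathway defaults
res = simulate(cfg)                              # 0..6 hr, 0.02 hr grid
df = res.to_frame()
print(df.iloc[[0, 25, 50, 100, 200, 300]]
        [["time_hr", "chamber_ppm", "c_liver", "a_met_liver", "a_met_linear"]]
        .to_string(index=False))
```

```
 time_hr  chamber_ppm  c_liver  a_met_liver  a_met_linear
     0.0   500.000000 0.000000     0.000000      0.000000
     0.5   166.855753 8.068599     1.943794      0.222651
     1.0    71.992174 3.531031     3.772874      0.362700
     2.0    14.160461 0.225015     6.326172      0.424871
     4.0     0.651970 0.008046     7.268212      0.430838
     6.0     0.036981 0.000459     7.322047      0.431107
```

The chamber concentration falls three orders of magnitude in 6 hours as the
three rats absorb and metabolise the dose; `a_met_liver` is one rat's
cumulative hepatic metabolism (mg) and `a_met_linear` the part flowing
through the linear GST term. Summing over animals, 23.5 mg of the 23.8 mg
dose is metabolised by 6 hr, with the GST pathway contributing 5.5% at this
exposure — the linear pathway is numerically small at intermediate
concentrations, exactly the regime where the two hypotheses are hardest to
distinguish. The mass-balance residual stays below 3e-15 relative.

Parameter estimation and sensitivity analysis from the shell:

```bash
bcmpbpk generate --noise-cv 0 --seed 0 --out chamber.csv
bcmpbpk fit --data chamber.csv --hypothesis two_pathway \
        --start 5.7,0.525,7.05 --out fit.json
bcmpbpk sense --parameter vmax --variable liver_concentration --out sens.csv
```

The `sense` command prints

```
liver_concentration sensitivity to vmax at 500 ppm: peak |S| = 5.694 at t = 1.54 hr
```

i.e. the liver concentration is most informative about Vmax roughly 1.5
hours into a 500 ppm experiment — an argument for short experiments with
liver sampling rather than 6-hour chamber-only runs. The same quantity for
`--variable chamber_air` peaks lower (|S| ≈ 2.5), so chamber data alone
carry less Vmax information than liver data would.

## Layout

| module | contents |
| --- | --- |
| `bcmpbpk.physiology` | F344 rat constants, closure rules, ppm↔mg/L conversion |
| `bcmpbpk.kinetics` | the two metabolic rate laws and their parameter types |
| `bcmpbpk.model` | chamber + tissue ODE system, stiff simulation, mass balance |
| `bcmpbpk.datasets` | synthetic uptake datasets, CSV round trip, provenance |
| `bcmpbpk.estimation` | log-space cost, Nelder–Mead fitting, error reports |
| `bcmpbpk.sensitivity` | normalized sensitivities, surfaces, identifiability |
| `bcmpbpk.cli` | `bcmpbpk` command: generate / simulate / fit / sense / surface / recover |

See `docs/methods.md` for the model equations, assumptions, numerical
choices and known limitations.
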