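# Methods

## Model structure

One adult F344 rat is described by five well-stirred, flow-limited tissue
compartments — adipose, rapidly perfused, slowly perfused, liver, kidney —
with lung and blood treated algebraically under a steady-state assumption.
For tissue *t* with volume `V_t`, blood flow `q_t` and tissue:blood
partition coefficient `P_t`:

    V_t dC_t/dt = q_t (C_art − C_t / P_t)          (− Met_t for liver, kidney)

The algebraic blood compartment gives the venous return
`C_ven = Σ_t q_t (C_t/P_t) / QC` and, with the steady-state lung,

    C_art = (QC·C_ven + QP·C_air) / (QC + QP/P_b)

where `QC = QCC·BW^0.75` is cardiac output, `QP = QV·QC` alveolar
ventilation and `P_b` the blood:air partition coefficient. Exhaled air is
alveolar, `C_exh = C_art/P_b`; there is no dead-space or diffusion
limitation. The sealed chamber holding `N` identical rats evolves as

    dA_ch/dt = N·QP·(C_art/P_b − C_air) − k_loss·A_ch,   C_air = A_ch/V_ch

Because the animals are identical, one rat's ODEs are integrated and the
body burden scaled by `N` in the chamber exchange; this is exact, not an
approximation. Cumulative amounts metabolised (per organ and through the
linear pathway) and leaked are carried as extra states, so total mass —
chamber + N·(tissue burden + metabolised) + leaked — is conserved by
construction; simulations close the balance at machine precision and the
test suite enforces ≤ 1e-6 relative.

## Metabolism

Both hypotheses split one body-level metabolic capacity between liver
(94.8%) and kidney (5.2%), applying the share to the whole bracketed rate —
so `Vmax` is a body-level constant, not an organ-intrinsic one:

* two-pathway: `Met_l = 0.948·(Vmax·C/(Km+C) + kGST·C·V_liv)` — saturable
  CYP2E1 plus first-order GST conjugation;
* two-binding-site: `Met_l = 0.948·(Vmax1·C + CL2·C²)/(Km1+C)` — a single
  enzyme whose effector site makes the rate asymptotically linear with
  slope `CL2` at high substrate. With `CL2 = 0` it degenerates exactly to
  Michaelis–Menten, which the tests exploit as a cross-hypothesis oracle.

Rate laws evaluate `max(C, 0)`: stiff solvers probe slightly negative
states near zero and the guard keeps the rates physical without altering
the converged solution.

## Parameters

Defaults describe a 0.25 kg adult F344 rat and the standard chamber design:

| symbol | meaning | default | units |
| --- | --- | --- | --- |
| BW | body weight | 0.25 | kg |
| QCC | allometric cardiac output coefficient | 15 | L/hr/kg^0.75 |
| QV | ventilation:perfusion ratio | 1.7 | – |
| q_adi, q_slw, q_kid, q_liv | flow fractions of QC | 0.082, 0.257, 0.138, 0.242 | – |
| V_slw, V_liv, V_kid, V_adi | volume fractions of BW | 0.674, 0.044, 0.0075, 0.112 | – |
| P_b | blood:air partition | 41.5 | – |
| P_liv = P_rap = P_kid | tissue:blood partitions | 0.7 | – |
| P_slw, P_adi | tissue:blood partitions | 0.267, 7.8 | – |
| V_ch, N, k_loss | chamber volume, rats, leak | 9 L, 3, 0.025/hr | |
| Vmax, Km, kGST | two-pathway kinetics | 3.8, 0.35, 4.7 | mg/hr, mg/L, 1/hr |
| Vmax1, Km1, CL2 | two-site kinetics | 3.7, 0.3, 0.047 | mg/hr, mg/L, L/hr |

Closure rules: the rapidly perfused compartment takes the flow remainder
`1 − Σq = 0.281` of QC and the volume remainder `0.91 − ΣV = 0.0725` of BW.
The modelled tissue mass is 91% of body weight; blood is the remaining 9%
and carries no differential state. The published source table writes the
rapidly-perfused flow row as `QV − Σq_i`, which is dimensionally
inconsistent with the fraction rows; we read it as the flow-fraction
remainder so that perfusion sums to cardiac output, which venous mass
balance requires.

Gas concentrations convert as `mg/L = ppm·MW/24450` (molar volume 24.45
L/mol at 25 °C); MW(CH₂BrCl) = 129.38 g/mol from standard atomic masses.
The chamber volume is used as printed (9 L) with no animal-volume
subtraction. Two printed variants of kGST exist in the source material
(4.5 and 4.7/hr); this package uses 4.7/hr, the value the primary results
text states, as its canonical set.

## Numerical integration

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-8, atol 1e-10, dense output
on a default 0–6 hr grid at 0.02 hr steps (the historical experiments span
about 6 hours). The system is only mildly stiff (the fastest tissue time
constant is ~30 s against a 6 hr horizon), but LSODA's automatic switching
makes the tight tolerances cheap. A fixed-step RK4 oracle at dt = 1e-4 hr
agrees with the stiff solution to better than 1e-5 relative, and a
closed-form partition-equilibrium limit (no metabolism, no leak) is matched
to 1e-6; both are frozen as tests.

## Synthetic data

The historical five-run design (starting concentrations spanning 200–4000
ppm) exists only as digitized figures, so the generator emulates it: the
PBPK model's own chamber curve at c0 ∈ {200, 500, 1000, 2000, 4000} ppm,
sampled every 0.1 hr from 0.1 to 6 hr (first sample after post-bolus
mixing, not at t = 0), with multiplicative lognormal noise
`c_obs = c_model·exp(ε)`, `ε ~ N(0, CV²)`, default CV 5%. Log-additive
noise is the natural conjugate of an estimator that works on ln(data); the
source material states no error model, and the true observation times and
starting concentrations of the original runs are unknown — the defaults are
a stand-in inside the printed range. The generator therefore emulates the
*structure* of real uptake data but not digitization artefacts, baseline
drift, or animal-to-animal variability: passing recovery tests show the
estimator is correct and the design identifying, not that real digitized
curves would yield these exact constants.

## Estimation

`cost(θ) = Σ_series Σ_obs (ln c_model − ln c_obs)²`, with the model run at
each series' exact observation times (no interpolation). Nelder–Mead
operates on ln θ — positivity without constraints, and sane steps for
constants spanning two orders of magnitude (CL2 ≈ 0.05 vs Vmax ≈ 4).
Convergence: simplex tolerance 1e-8 (log scale), cost tolerance 1e-10, at
most 2000 evaluations per start. Multi-start (components jittered by
U(0.5, 2), seeded) is available but off by default: with the log transform
and these designs a single run from any reasonable start converges, and
restarts multiply runtime several-fold. Observations ≤ 0 (possible under
heavy noise) are excluded from the cost with a logged count. The
Monte-Carlo noise study relaxes the simplex tolerance to 1e-4 — parameter
precision far below the noise floor — which cuts the per-fit cost roughly
tenfold without moving the estimates.

The per-series "rmse" is reported exactly in the source's printed
convention, `‖c_model − c_obs‖₂ / n_obs` (not the conventional
`√(‖·‖²/n)`), in ppm, and relative to each series' starting concentration.

## Sensitivity analysis

`S(t) = (p/y)·∂y/∂p` for `y` ∈ {chamber air, liver concentration} and any
scalar parameter in the configuration (metabolic, physiological, partition,
chamber). Default route: central finite differences with relative step
1e-4 at tightened solver tolerances (rtol 1e-10), since trajectory
differencing amplifies integration noise. Verification route: forward
sensitivity integration of the augmented system
`s' = (∂f/∂y)s + ∂f/∂p`, with Jacobian-vector products formed by central
differencing of the right-hand side itself — independent of the trajectory
differencing. The two agree to 1e-4 relative wherever |S| > 1e-6, and
halving the step moves S by under 1% (Richardson check). Where
|y| < 1e-12 mg/L the normalization is singular and S is defined as 0; at
t = 0 every S is 0 because the initial state contains no parameter.
Physiological perturbations (BW, QCC, fractions) re-derive the closure
rules, so sensitivities are of the self-consistent model.

Surfaces divide a parameter range into n subintervals (n+1 grid values,
endpoints included) and recompute the full time course at each value —
e.g. Vmax over 2.5–4.5 mg/hr at 500 ppm, bracketing the canonical 3.8.
Peak times are grid argmaxes of |S| at the 0.02 hr output resolution.
Signed coefficients are emitted; peak detection uses |S|.

Identifiability: columns of normalized sensitivity time courses are
assembled into a matrix and summarised by singular values, condition
number, and a per-column same-sign flag (a set of same-sign columns cannot
sum to zero, the classical sufficient hint for local uniqueness). The
check is diagnostic — no hard threshold — except that exact rank
deficiency (duplicated or dead parameters) is detectable exactly.

## Design choices on open points

* The three metabolic parameters are the only fitted quantities; physiology
  and partitions are fixed constants, mirroring the original analysis.
* The acceptance surface is parameter recovery on synthetic data because
  the original digitized observations were never deposited; recovered
  values agree with the generating truth to ~1e-8 relative noise-free.
* The GST share of total metabolism is reported by the pipeline (5.5% of
  the metabolised dose at 500 ppm over 6 hr with the defaults) but not
  asserted: the claim that it stays below 5% is concentration-dependent
  and the linear term dominates arithmetically at high exposure.
* Problem sizes in the test suite (three-series coarse-grid fits for unit
  tests, full five-series design for the acceptance experiments, 20
  replicates for the noise study) were chosen as the smallest studies that
  still exercise each claim at its stated tolerance.

## Known limitations

* Local (one-at-a-time) sensitivity only; no Sobol/Morris global analysis.
* Flow-limited tissues only; no diffusion limitation, dead space, oral or
  dermal routes, and no human extrapolation.
* The noise model is i.i.d. multiplicative lognormal; real digitized
  uptake data have correlated, heteroscedastic digitization error.
* `fminsearch`-style simplex minimisation offers no uncertainty
  quantification; the Hessian positive-definiteness check is a local
  identifiability statement, not a confidence region.
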