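# Methods

## The model

`irontraffic` implements a coarse-grain kinetic model of iron trafficking in
an exponentially growing budding-yeast cell. Eight components — the cytosolic
labile Fe(II) pool (FC), cytosolic/nuclear iron destinations (CIA), vacuolar
Fe(II) and Fe(III) (F2, F3), the mitochondrial labile pool (FM), mitochondrial
iron-sulfur clusters and hemes (FS), mitochondrial ferric phosphate
nanoparticles (MP), and matrix dissolved O2 — react through nine reactions
with parsimonious rate laws: saturating (Michaelis-Menten) import and
transfer steps, a bilinear mass-action nanoparticle step, a linear O2
exchange with the environment, a catalytic respiration step (FS as catalyst),
and an O2-inhibited iron-sulfur assembly step gated by the factor
[O2]_sp/([O2]_sp + [O2]). Every concentration is local to its compartment
(cytosol 0.8, mitochondria 0.1, vacuole 0.1 of cell volume); interregional
fluxes carry the factor f_cyt/f_mit = f_cyt/f_vac = 8 so mass is conserved.
Each ODE carries a dilution term −α_cell·[C_i] for growth. External nutrient
levels [IRON] and [OXYGEN] are held fixed.

Reactive oxygen species, explicit enzymes, and spatial structure are outside
the model by construction.

## Steady-state parameterization

Instead of fitting rate constants to time series, the package derives them
from steady-state concentrations. Writing the system as S·R = C′ with the
8×17 stoichiometric matrix over the 9 reaction rates and 8 dilution
pseudo-rates, the steady-state condition S·R = 0 is solved by exact rational
reduced-row-echelon form (sympy): 8 pivot columns mark the dependent rates
and 9 free columns the independent ones (the respiration rate R_res and the
8 dilution rates). Given measured concentrations, a growth rate, and one
literature-informed choice of R_res, all dependent rates follow from the
null-space relations, and each rate constant is obtained by inverting its
rate law (every rate law is linear in its constant). Michaelis constants
default to the healthy-state substrate concentration; the iron-import K_m
uses 10 μM rather than the substrate level of 40 μM (the adjusted published
value).

Two conventions matter for reproducing the published constants exactly:

* **Shared respiration constant.** k_res is derived once from the reference
  (healthy, W) state and held state-independent. For the other states the
  matrix [O2] is *back-solved* from R_res = k_res·[FS][O2]/(K_res+[O2])
  rather than read from the concentration table — this is the only way the
  published k_mp, k_O2 and D_O2 values close, and it implies
  [O2]_Y = 0.48133 and [O2]_D = 1.22222 behind the rounded printed values
  0.48 and 1.2. Consequently the D state's simulated [O2] deviates 1.85%
  from the *printed* value — a printing artifact (1.2222 prints as "1.2" at
  two significant figures), not a dynamics error; all iron species match
  well within 1%.
* **Growth-rate truncation.** α_cell is the printed truncation 0.003333
  min⁻¹, not 1/300, because the published dilution rates were computed with
  the truncated value. The frataxin-deficient growth rate is 0.002 min⁻¹ (the
  value the published tables encode).

## Regulation

Rate constants are regulated by soft-Heaviside logistic valves,
k_obs = k_reg/(1 + e^{n([SP]−[Sen])}) + k_unreg, with a model component as
sensor. Valves are fitted to the three per-state (sensor concentration,
rate constant) points by deterministic multi-start trust-region least
squares: a fixed grid of sensitivities (scaled to the sensor span, both
signs) crossed with setpoint starts, plus a few seeded random starts; an
inner linear solve supplies nonnegative (k_reg, k_unreg) starting values.
Four parameters against three points make the fit non-unique at the
parameter level; the contract is curve-level agreement. Selection among
converged fits: smallest residual, ties broken by smallest |n| (gentlest
valve), then setpoint closest to the mean sensor concentration. The setpoint
is constrained to (0, 10000] inside the optimizer, and exponent magnitudes
above 700 saturate instead of overflowing. A valve whose best fit misses any
point by more than 0.1% relative is excluded from the pool with a recorded
reason.

## Dynamics

The stiff system is integrated with LSODA (scipy's `odeint`) using the
analytic Jacobian, rtol = atol = 1e-8. When no output grid is requested, a
17-point logarithmic grid spans the horizon — a single enormous output
interval degrades LSODA's step-size control. A steady state is *defined
operationally* as the t = 50,000 min endpoint (≈ 240 doublings at the
healthy growth rate); an algebraic Newton root of the right-hand side is
kept as a cross-check oracle only. Rate laws clip transiently negative
concentrations at zero.

Transitions: the healthy→diseased switch abruptly reduces the iron-sulfur
assembly constant 10× and moves the growth rate along the linear map through
(6.666, 0.003333) and (0.6666, 0.002); healthy→iron-deficient lowers external
iron 40 → 1 μM; hypoxic predictions lower external oxygen from 100 to 25 or
1 μM. Steady-state (quasi-static) transitions move the trigger parameters
linearly over 100 increments, each re-equilibrated for 50,000 min,
warm-started from the previous increment (a cold-start mode reproduces the
literal protocol). A per-increment convergence flag compares the residual
derivative to the dilution flux; non-convergent increments disqualify a
candidate mechanism downstream. Perturbation-recovery multiplies one
concentration at a chosen time and reports the first time all components
return within 1% (configurable) of the steady state.

## Stability and sensitivity

The 8×8 Jacobian is assembled analytically (chain-rule terms through the
valves included when a regulatory mechanism is active) and verified against
central finite differences. A state is stable iff all eigenvalues have
negative real part. The Jacobian keeps the O2-inhibition factor in the FM
equation's assembly term: the published Jacobian-function table omits it
there, but the published rate balances and all 24 published eigenvalues
(three states, to every printed digit) only close with the factor included;
an as-printed variant is available for comparison
(`jacobian(..., fm_row_o2_factor=False)`) and is not stable for any choice
of respiration rate. For the same reason the reported instability of the
initially considered R_res = 10,000 μM/min cannot be regenerated: with the
consistent Jacobian the healthy state's slow spectrum is invariant to R_res
(the respiration constant scales the O2 self-damping and the FS→O2 coupling
proportionally). Note also that R_res = 10,000 is infeasible for the
frataxin-deficient state (k_res·[FS] = 6000 < R_res forces a negative [O2];
the builder raises an inversion error).

Sensitivity of a rate constant: scale the constant — its regulated and
constitutive parts alike — by h, re-equilibrate, and let G_i(h) be the
percent change of steady-state [C_i]. The score is the mean over components
of |dG_i/dh| at h = 1 by the standard five-point stencil with step j = 0.01.
The printed stencil's sign on the G(h+2j) term and its trailing [C_i] factor
are treated as typos (percent normalization already carries the
concentration); strict as-printed modes are provided.

## Selection of regulatory mechanisms

Candidate cellular regulatory mechanisms (CRMs) — one sensor per regulatable
reaction — pass six sequential filters:

1. **Uniqueness**: only reactions with pairwise-distinct constants across
   the three states are regulatable; the iron-sulfur assembly constant is
   additionally locked as the primary mutation and the respiration constant
   is state-invariant, leaving 7 of 9 reactions (8⁹ = 134,217,728 mechanisms
   reduce to 8⁷ = 2,097,152).
2. **Trending**: a sensor must order strictly with (feedforward) or against
   (feedback) the constants across states. The survivor count is the product
   of per-reaction counts (576 for the bundled tables), cross-checked by
   brute-force enumeration of all 8⁷ assignments.
3. **Targeting**: each candidate, assembled from the fitted valve pool,
   starts at its own self-consistent healthy steady state and must land
   every component within 1% of the target state after both abrupt
   transitions. Targets are the full-precision state profiles (with
   back-solved [O2]); against the printed table no mechanism could pass the
   iron-deficient transition, for the rounding reason above.
4. **Wandering**: per-component polyline arc lengths of the transition paths
   — in (t, C) coordinates over the first 5000 min for time mode, in
   (trigger parameter, C) coordinates over the 100 increments for
   steady-state mode — are compared with the straight endpoint-to-endpoint
   distance (the minimal arc length; the source leaves it undefined), and
   the percent excess is averaged over components, then over the two
   transitions for each mode. The lowest-error half of each mode is kept and
   the halves intersected.
5. **Smoothness**: 100·Σ_j |C(j)−C(j+1)|/C(j) summed over components and
   both steady-state transitions (zero concentrations floored at 1e-12 μM);
   mean-shift clustering (scikit-learn) of the scores keeps the cluster
   containing the smoothest candidate.
6. **n/SP-reasonableness**: |n|−1 (or |1/n|−1) and the setpoint's relative
   distance from the mean sensor concentration are scored and reported;
   survivors are ordered by the combined score.

Arc lengths are computed on raw local concentrations, as the error formulas
are written; a normalized mode would change absolute scores but the filter
only uses ranks.

### What the pipeline does and does not reproduce

Filters 1–2 are exact combinatorics and reproduce the published counts
(2,097,152; 576) identically. Filters 3–4 depend on the numerical quality of
the valve fits: our multi-start fits reproduce all 20 trending-valid valves
essentially exactly (worst point misfit < 1e-9 relative), so *more*
mechanisms reach their targets than in the original study, whose single-start
regression internals (and its pool of 18 of the 20 valves, with the two
exclusions unidentified) are not specified. The published survivor counts
(146 after targeting, 26 after wandering) are therefore not recovered
exactly; the package reports its own counts together with every
per-candidate score. The structural result is robust: the two published
mechanisms — identical except for the iron-import sensor (FC vs F2), with
feedforward FC control of vacuolar import and oxidation and feedback FS
control of mitochondrial import — survive every filter and rank in the final
smoothest cluster.

## Problem sizes and determinism

The full cascade integrates ≈ 1,700 transition endpoints for targeting and
≈ 2×100 increments per wandering survivor; it runs in roughly ten minutes on
one CPU with the analytic-Jacobian LSODA path. All randomness (the extra fit
starts) flows from a single integer seed; reruns with the same seed are
bit-identical. Mean-shift clustering and all filters are deterministic.

## Known limitations

* Identifiability is not addressed (nor was it in the source study); the
  parameterization is exact by construction, not statistically estimated.
* The wandering/smoothness scores mix units (minutes vs μM; μM vs μM/min on
  the abscissa) exactly as the defining formulas do; they are used only for
  ranking.
* Survivor counts at filters 3–4 are regression-policy-dependent (above).
* The published sensitivity table's magnitudes are not recoverable from the
  stated percent-change/stencil construction (its k_23 entry is near zero,
  while a 1% change in k_23 necessarily moves [F2] by ≈1.8% at
  half-saturation); under our construction the oxygen-import constant is the
  most sensitive in every state, as published, but the least-sensitive slot
  varies between k_23 and k_mp.
* The hypoxic FS "≈5× higher than diseased" remark in the source conflicts
  arithmetically with its own table (273 vs 150 μM, a factor 1.8); the
  package reports the simulated values and leaves the reconciliation to the
  reader.
* User-defined networks are supported through the structured-text model file
  (seven rate-law kinds, arbitrary compartments/components), but the
  selection pipeline assumes exactly three trained states and the two
  transition triggers of the bundled study design.
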