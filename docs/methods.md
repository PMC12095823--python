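# Methods

## The model

`commscreen` simulates batch growth of one or more genome-scale (or toy)
metabolic models sharing a single well-mixed extracellular pool, using the
static-optimisation formulation of dynamic flux balance analysis (dFBA).
Time is discretised into steps of length Δt. At every step each species *i*
solves its own FBA linear program

  max_v cᵀv   s.t.  A·v = 0,  v_l ≤ v ≤ v_u

where *A* is the m×n stoichiometric matrix, *c* the indicator of the
biomass reaction, and the exchange-flux sign convention is negative =
uptake from the pool, positive = secretion into it. There is **no**
community-level objective: each organism independently maximises its own
growth, and all interactions emerge from competition for, and secretion
into, the shared pool. Secreted metabolites become available to every
species at the next step.

Because the growth LP is usually degenerate away from the objective, the
returned flux vector is the *parsimonious* solution: total absolute flux is
minimised at the fixed growth optimum (pFBA). This removes arbitrary
alternate optima from the pool update and makes trajectories deterministic.

### Substrate uptake bounds

The uptake bound for species *i* on pool metabolite *j* combines what is
physically available with saturable transport:

  v_s = min( S_j / (X_i·Δt),  V_max·S_j / (K_m + S_j) )

with S_j the pool concentration (mmol/L), X_i the species biomass (g/L).
The first term is the amount of nutrient importable per gram biomass within
one step; the second is Michaelis–Menten transport. Uniform kinetics
(V_max = 20 mmol/gDW/h, K_m = 0.05 mmol/L) are applied to every metabolite
by default, with optional per-metabolite overrides.

Since each species sizes its availability term with its **own** biomass,
aggregate demand can exceed the pool. After all LPs are solved, any
oversubscribed metabolite's uptake bounds are tightened proportionally to
each species' realised share (so the step consumes exactly the pool
content) and the affected LPs are re-solved once. Residual negatives within
solver tolerance are clipped to zero and logged; on the fixture networks
the clipped mass is below 1e-6 mmol/L (asserted in tests).

### State update and product tracking

Forward Euler:

  X_i ← X_i·(1 + μ_i·Δt)    S_j ← S_j + Σ_i v_ij·X_i·Δt

Product formation is tracked on two ledgers, kept deliberately separate:

* the **pool ledger** evolves from the parsimonious solutions' actual
  secretion fluxes (these products stay in the pool and may be re-consumed);
* the **production-potential ledger** P_{k,i} accrues, per species and
  product, the maximum product-exchange flux found by a per-step flux
  variability analysis (FVA) with the biomass flux constrained to at least
  a fraction (default 0.999) of the step optimum:
  P_{k,i} ← P_{k,i} + v_{p_k}·X_i·Δt.

Screening metrics use the potential ledger (FVA upper bounds compare
systems fairly when secretion is degenerate); the medium evolves from the
growth solutions. Holding biomass at 99.9 % rather than 100 % of the
optimum avoids numerical brittleness at the LP vertex; the fraction is
configurable.

An infeasible per-step LP (e.g. an unsatisfiable maintenance demand after
substrate exhaustion) gives that species μ = 0 and zero fluxes for the
step; it remains in the pool. The terminal state reported for a run is the
mean over the last five time points at which at least one species' LP was
feasible — a cheap guard against end-of-run solver noise. Abundances are
terminal biomass fractions, Abundance_i = X_i / Σ X_i.

## Screening layer

* **Productivity** of a system for a product: terminal averaged cumulative
  product concentration divided by the batch horizon (mmol/L/h). The
  divisor is the full horizon; with the default 12 h batch this reproduces
  the familiar titre/12 reading.
* **Productivity gain**: Δ = P(Comm_AB) − max(P(Mono_A), P(Mono_B)) and
  ratio = Δ / |max(P(Mono_A), P(Mono_B))|. The co-culture is always
  benchmarked against the *best* monoculture. When the best monoculture is
  below 1e-6 mmol/L/h and the community exceeds ten times that floor, the
  ratio is reported as the sentinel category "high" instead of a number.
* **Interaction type**: each member's growth in co-culture is compared
  with half its monoculture growth using a ±10 % band — positive if
  Comm > 1.1·Mono/2, negative if Comm < 0.9·Mono/2, else no change — and
  the unordered sign pair maps to competition (−/−), amensalism (−/0),
  parasitism (+/−), neutralism (0/0), commensalism (+/0), mutualism (+/+).
  The growth measure defaults to terminal averaged biomass (that is what
  screen tables report); a terminal averaged growth-rate measure is
  available. A species with zero monoculture growth measure is reported as
  "undefined" rather than forced into the six-way map.
* **Viability**: every member must keep terminal abundance ≥ 0.1 and gain
  ≥ 10 % biomass over its inoculum (per-member by default; a total-biomass
  mode exists).
* **Cross-feeding**: each species' exchange fluxes are integrated with its
  biomass over the run; net secretion above tolerance marks a Producer, net
  consumption a Consumer, and a metabolite is cross-fed when both roles
  coexist in one trajectory.
* **Scans**: pairwise screens across environments (with obligate
  aerobe/anaerobe exclusion flags consulted as model metadata, never
  inferred from the network), carbon-source swaps (the primary carbon is
  replaced at 10 mmol/L, everything else untouched), inoculum-ratio sweeps
  at fixed total inoculum, and a Latin-hypercube sensitivity scan of
  (V_max, K_m) with one simulation per draw and an OLS regression of
  terminal community biomass on the raw parameters (coefficients also
  reported on z-scored predictors; R² is defined as 0 when the response
  does not vary).

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| Δt | 0.1 | h | 120 steps over a 12 h batch; halving Δt moves toy terminal biomass < 2 % (tested) |
| horizon | 12 | h | carbon source fully consumed and stationary phase reached on the fixtures |
| initial biomass | 0.01 | g/L per species | small but numerically safe inoculum; monoculture baselines use the same value as each co-culture member |
| V_max | 20 | mmol/gDW/h | within the reported range for sugar transporters |
| K_m | 0.05 | mmol/L | typical high-affinity transport constant |
| FVA growth fraction | 0.999 | – | near-optimal growth without vertex brittleness |
| averaging window | 5 | feasible points | terminal-state smoothing |
| interaction threshold | 0.1 | – | ±10 % band around Mono/2 |
| viability | abundance ≥ 0.1, growth ≥ 10 % | – | both members must contribute and grow |
| LHS ranges | V_max 1–50, K_m 0.01–1, n = 10 | – | spans the plausible transport-kinetic space |

Media components default to 10 mmol/L each; aerobic environments add
10 mmol/L oxygen, anaerobic ones none. Unit conversions between g/L and
mmol/L use molar masses computed from metabolite formulas (glycerol's
92.09 g/mol is shipped as a fixture constant); metabolites without formulas
are excluded from mass-based reporting.

## The toy community

Real screens run on genome-scale models; the shipped fixtures are three
hand-built networks whose behaviour is checkable by hand and by an
independent scipy-based LP oracle:

* **toy_a** grows on glucose (40 hexose units per gDW) behind a shared
  importer capacity of 15 mmol/gDW/h and *obligately* dumps 20 mmol acetate
  per gDW into the pool through its biomass stoichiometry. Once glucose is
  exhausted it salvages extracellular acetate (net 20 mmol/gDW after its
  own re-dumping). The salvage pathway is deliberately one enzymatic step
  longer than direct glucose catabolism so that parsimonious flux selection
  secretes the overflow while glucose lasts instead of short-circuiting it
  internally; the shared importer capacity removes any growth advantage
  from doing so. It can divert hexose units to product P1.
* **toy_b** cannot touch glucose and grows only on acetate (20 mmol/gDW),
  making product P2. Its monoculture on glucose media is exactly zero
  growth, so any co-culture growth is attributable to cross-feeding.
* **toy_c** competes for glucose with toy_a's yield and capacity, secretes
  nothing, and wastefully imports acetate (100 mmol per internal hexose
  unit).

These constructions give analytically known ground truths: toy_a+toy_b is
cooperative (commensal or mutualistic depending on how the acetate pool
splits) with toy_b viable only in co-culture; toy_a+toy_c is antagonistic
(amensal/competitive) because toy_c both halves toy_a's glucose and
squanders the acetate toy_a would otherwise salvage — a deliberately
super-linear loss, since with a single shared resource the FBA value
function is positively homogeneous and an even split would land every
member exactly at the neutral band's centre. A dense-inoculum variant
(200 g/L) makes the availability term bind for every kinetic draw and is
used to demonstrate the sensitivity scan's null result.

What the toys do **not** emulate: elemental mass balance (reactions are
caricatures), maintenance energy, respiration/oxygen chemistry, pH or
by-product inhibition, and the sheer degeneracy of genome-scale flux
spaces. Passing tests therefore demonstrate the *engine's* bookkeeping,
conservation and decision logic — not predictive accuracy for any real
organism.

## Numerical choices

* LP backend: GLPK through cobra/optlang; deterministic, so identical
  configurations reproduce trajectories bit-for-bit (asserted in tests).
  Brute-force cross-checks in the test suite use scipy's HiGHS `linprog`
  on independently assembled matrices.
* Concentrations below the LP tolerance (1e-9) are treated as zero when
  deriving uptake bounds.
* A community of one is the monoculture code path — there is no separate
  implementation to drift apart.
* Fed-batch: after each step, if the watched substrate falls below the
  trigger (g/L) it is reset to the target; every event is time-stamped and
  enters the substrate budget used by yield calculations.
* Yield (g/g) = produced·M_product / (consumed·M_substrate), with consumed
  = initial − terminal + fed; undefined (NaN) when nothing was consumed.

## Known limitations

No spatial structure, lag phases, death or maintenance decay beyond what a
model encodes, and no regulatory or enzyme kinetics: uptake is uniform
Michaelis–Menten. The quasi-steady-state assumption ignores transient
intracellular pools. The one-pass oversubscription correction conserves
mass but can leave a species marginally under its fair share in the step
where a metabolite runs out. Exhaustive screens are quadratic in the
number of organisms; the engine accepts N species but the screening layer
targets pairs.
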