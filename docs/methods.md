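# Methods

This note documents the models implemented in `crococompete`, the parameter
choices and their provenance, what the synthetic-data generator does and does
not emulate, and the numerical and design decisions a maintainer would want
to know.

## Growth model and parameters

Phytoplankton growth is nitrogen-specific: pools and the currency of
competition are cellular nitrogen (nmol N L⁻¹), rates are d⁻¹, time is in
days, and nutrient concentrations nmol L⁻¹ throughout. The specific growth
rate is a sum of independent Monod terms over NH₄⁺ and NO₃⁻; there is no
interaction between the nutrients (no ammonium inhibition of nitrate uptake)
and no cap beyond the sum of the two maxima. Urea, phosphorus and iron
limitation are out of scope.

Two default groups are shipped:

| parameter | Cro | Oth | provenance |
|---|---|---|---|
| V_max^NH4 (d⁻¹) | 6.6 | 1.1 | literature values for this system |
| V_max^NO3 (d⁻¹) | 3.0 | 0.8 | package default (literature states only that the diazotroph's NO₃⁻ maximum is the higher) |
| K^NH4 (nmol L⁻¹) | 500 | 50 | package default (see below) |
| K^NO3 (nmol L⁻¹) | 500 | 100 | package default |
| mortality m (d⁻¹) | 0.1 | 0.1 | package default |
| diazotroph floor (d⁻¹) | 0.31 | — | literature value |

The half-saturation constants are not printed in the sources this model
follows; the defaults encode the qualitative mechanism those sources
describe — *Crocosphaera* couples high uptake maxima to high half-saturation
constants, so it dominates when combined N is ≳100 nmol L⁻¹ but loses to
high-affinity picoplankton at ~1 nmol L⁻¹ unless N₂ fixation sustains it.
With these defaults the three canonical scenarios reproduce exactly that
pattern. All values are overridable in the YAML config, and the defaults are
echoed into every run manifest so "literature value" vs "package default"
provenance stays visible.

The diazotrophic floor applies to the *realized growth rate* before
multiplication by N (μ = max(μ_Monod, 0.31) when fixation is enabled), not as
an additive nitrogen source term. It is a per-group optional attribute, so
other diazotroph groups can carry their own floor.

## Ecosystem model

Grazing uses the kill-the-winner response: pressure on each prey is weighted
by its squared share of the prey community, times a saturation term in total
prey. The 0/0 case with no prey is defined as zero grazing, and the
degenerate K_G = 0 (saturation → 1) is allowed. Zooplankton suffer quadratic
mortality. Phytoplankton linear mortality appears only in the incubation
model; in the ecosystem model grazing is the loss term. Nitrogen lost to
grazing appears one-for-one in the zooplankton pool, so the total-N budget
closes exactly and is audited on every stored trajectory.

Scenario nutrients are held **constant** (100/100 or 1/1 nmol L⁻¹) rather
than depleted: the scenarios are defined by their concentrations and no
nutrient dynamic is part of the model. This is a declared modelling
assumption, as is the default duration of 10 d and the default initial state
(N_Cro = N_Oth = 1, N_zoo = 0.1 nmol N L⁻¹) — neither is a literature value.
Default zooplankton parameters (G_max = 1.0 d⁻¹, K_G = 5 nmol L⁻¹,
m_zoo = 0.1 (nmol L⁻¹)⁻¹ d⁻¹) are likewise package defaults. No diel cycle is
modelled (real *Crocosphaera* fixes N₂ at night).

## Numerics

Integration is classical fixed-step RK4 with default dt = 0.01 d:
deterministic, reproducible, and accurate for these smooth systems (the
closed-form exponential at μ = 1.9 d⁻¹ is recovered to ~2×10⁻⁹ relative at
t = 1 d; step-halving changes shipped-scenario finals by < 0.1%). Pools are
clipped at zero after each step; a non-finite state raises an error naming
the step. Quadratic nutrient forcings are clipped at zero on evaluation
since a fitted parabola can dip negative late in the window. Negative
nutrient inputs to the rate functions are rejected, not clipped — clipping
is the forcing's job.

## Forcing fits and censoring

The nutrient forcing for incubation replication is an ordinary least-squares
quadratic in time per nutrient. Values at or below the detection limit
(6 nM NH₄⁺, 3 nM NO₃⁻+NO₂⁻, 3 nM SRP) are left-censored; the default
substitution is limit/2, with `exclude` and `zero` as configurable
alternatives. Budget endpoints below detection are likewise substituted at
limit/2 and flagged in the output.

## Biomass estimation chain

Cell size calibration is log-log linear OLS of bead diameter on forward
scatter over the five bead standards (1.75, 2, 3, 6, 10 μm). Extrapolation
below the smallest bead is allowed but flagged — *Prochlorococcus* scatters
below that range, so its absolute biomass carries the largest size
uncertainty. Cells are modelled as spheres (V = π/6·d³); this is the minimal
assumption consistent with a scalar size summary, and the per-population
size summary is the replicate median of forward scatter (robust to
outliers). Carbon conversion is 235 fg C μm⁻³ for the cyanobacteria and the
modified Strathmann power law (log₁₀C(pg) = 0.94·log₁₀V − 0.6, converted to
fg only at the boundary) for picoeukaryotes; carbon→nitrogen uses the group
C/N molar ratios with 12.011 g mol⁻¹ for the fg→fmol step.

The acetylene-reduction conversion (4 mol C₂H₄ : 1 mol N₂) is exposed in
both units — N₂ or N atoms — because downstream budgets need N atoms while
the ratio itself is stated in N₂; the default output is N atoms and the
fixation-share computation uses N atoms consistently. "N demand" of the
diazotroph over an interval is **gross assimilation**: the net biomass-N
increment plus the mortality loss ∫m·N dt (configurable to net-only). With
the default generator (m = 0) the two coincide.

## Synthetic-data generator

The generator forward-simulates a 4-group community (Pro, Syn, PicoE, Cro)
through the same Monod growth model, coupled to nutrient depletion: the
drawdown rate is the community's net N assimilation divided by
(1 − sink_fraction). With the default sink of 0.5 the biomass increments
explain exactly half of the consumed N before noise — the unexplained half
stands in for luxury uptake and size-estimation gaps, making the "about
half" budget a tunable truth rather than an emergent accident. Generator
mortality defaults to zero (grazers are removed by 1-μm prefiltration and
the window is 3 days), which also keeps the drawdown monotone.

Study-design defaults: four treatments (control, +100 nM NH₄⁺, +100 nM
NO₃⁻, +10 nM P as a no-N-effect control arm; the urea treatment is not
modelled and not generated), days 0–3 sampled daily in triplicate, ambient
nutrients 15/5/60 nM (NH₄⁺/NO₃⁻/SRP) as in an oligotrophic subtropical
surface mixed layer, day-0 abundances 3×10⁴, 2×10³, 3×10², 10² cells mL⁻¹
(Pro, Syn, PicoE, Cro) with median diameters 0.6, 1.0, 2.0, 3.5 μm — chosen
so the largest-celled diazotroph holds the majority of community biomass N
while remaining rare by count. With these conditions the added ammonium is
drawn below the 6 nM detection limit by day 3 and flagged censored.

Noise is multiplicative lognormal (σ = 10% default) on abundances,
concentrations and ethylene rates — counts and concentrations are positive
and right-skewed — plus a small lognormal jitter (σ = 3%) on the replicate
median diameter that propagates through the d³ volume scaling. Each table
draws from its own random stream split from the master seed, so adding a
table never perturbs existing draws and regeneration is byte-identical per
seed.

N₂ fixation is generated as a specific rate of 0.007 d⁻¹ (N atoms per unit
biomass N) suppressed by ambient NH₄⁺ (up to 80%, half-effect at 100 nM),
which places the fixation share of the diazotroph's N demand at ~8% in the
control and ~1.5% under +NH₄⁺ — within the ranges reported for such
experiments. Fixation is *not* added to the generated growth (a ≲8%
inconsistency accepted for simplicity), and the measured share is a ratio
with a small, noisy denominator, so it scatters substantially (roughly
5–20% in the control across seeds at default noise).

What the generator does **not** emulate — hence what passing tests do not
show about real data: event-level flow cytometry and gating, the
forward-scatter/size nonlinearity of real instruments (Mie scattering),
filtration losses of large cells, diel fixation cycling, water-mass changes
between bioassays, and any P or Fe effect (the P arm is a pure control).

## Parameter fitting and identifiability

Fitting minimizes the sum of squared residuals between the RK4-integrated
model and observed cellular-N series (optionally in log space) with
multistart L-BFGS-B; starts come from a seeded Latin hypercube over the
bounds and half-saturation constants are searched in log₁₀ space. The best
loss is the minimum over starts and is reproducible for a fixed seed;
at-bound solutions are flagged.

A single drawdown curve identifies V_max and K jointly only when the
nutrient trajectory crosses K. For the default *Crocosphaera*
parameterization (K = 500 nM, concentrations ≤ 115 nM) the data sit in the
sub-saturating regime: the V–K loss surface has a flat ridge along constant
V·S/(S+K), every multistart converges to the same ridge, and V_max alone is
unidentifiable unless K is fixed. With K fixed, V_max is recovered to
machine precision from noise-free data and to a few percent from 5%-noise
triplicates. For the low-K group (K = 50 nM, crossed by the drawdown) both
parameters are identifiable, with 2-parameter errors of order tens of
percent at 5% noise and four time points — the recovery tolerances frozen in
the tests come from that build-time simulation. `profile_loss` exposes the
ridge for any free parameter.

## Known limitations

- The incubation and ecosystem models share the growth law but are not
  coupled; no scenario depletes its nutrients.
- The ecosystem model has two prey; the four-group community exists only on
  the observation side.
- Budget ratios use replicate means at interval endpoints; no uncertainty
  propagation is performed on the budgets.
- The fitting harness is least-squares only (no posterior inference), and
  fits one group at a time.
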