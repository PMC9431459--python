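# crococompete

Quantitative tools for studying *Crocosphaera watsonii* — a unicellular marine
N₂-fixing cyanobacterium — as a **competitor for combined nitrogen** (NH₄⁺ and
NO₃⁻), not just a nitrogen supplier. The package targets researchers working
with nanomolar nutrient-addition microcosm experiments and simple plankton
competition models: it couples a Monod-uptake growth model fitted to
incubation data with a kill-the-winner (KTW) grazing ecosystem simulator, and
a flow-cytometry-based cellular C/N biomass estimation and nitrogen-budget
chain. A seeded synthetic-data generator reproduces the statistical structure
of such an experiment end to end, so every stage is testable without any
cruise data.

## The models

**Incubation growth.** Each phytoplankton group *i* (the diazotroph `Cro` and
the aggregate of other phytoplankton `Oth`) follows

    dNᵢ/dt = (μᵢ − mᵢ) Nᵢ,
    μᵢ = V_max,i^NH4 [NH₄⁺]/([NH₄⁺]+K_i^NH4) + V_max,i^NO3 [NO₃⁻]/([NO₃⁻]+K_i^NO3)

with Nᵢ the cellular nitrogen pool (nmol N L⁻¹), mᵢ a linear mortality
(d⁻¹), and the ambient nutrients an exogenous forcing — either constant or a
quadratic in time fitted by least squares to measured drawdown (with
left-censored values below the detection limit substituted at half the
limit). *Crocosphaera* carries the high uptake maxima
(V_max^NH4 = 6.6 d⁻¹ vs 1.1 d⁻¹ for the others) but also the higher
half-saturation constants.

**Ecosystem competition.** Two prey compete under a zooplankton pool with
active prey switching (kill-the-winner):

    dNᵢ/dt    = μᵢ Nᵢ − Gᵢ N_zoo
    dN_zoo/dt = (G_Cro + G_Oth) N_zoo − m_zoo N_zoo²
    Gᵢ        = G_max · Nᵢ²/(N_Cro²+N_Oth²) · N_tot²/(N_tot²+K_G²)

When nitrogen fixation is enabled, the realized growth rate of the diazotroph
never falls below the diazotrophic floor μ_Cro = 0.31 d⁻¹ — fixation sustains
growth when combined N is depleted. Integration is fixed-step RK4.

**Biomass estimation.** Bead standards (1.75–10 μm) calibrate a log-log
linear map from forward scatter to cell diameter; spherical volumes convert
to carbon with 235 fg C μm⁻³ (cyanobacteria) or the modified Strathmann power
law log₁₀C(pg) = 0.94·log₁₀V − 0.6 (picoeukaryotes), then to nitrogen via
group C/N molar ratios (9.1 Pro, 8.6 Syn, 8.7 Cro, 6.6 PicoE). Acetylene
reduction rates convert to fixed N at 4 mol ethylene : 1 mol N₂.

## Worked example

Run the three canonical competition scenarios with default parameters
(initial pools N_Cro = N_Oth = 1, N_zoo = 0.1 nmol N L⁻¹, 10 days):

```python
from crococompete import scenario_suite
from crococompete.config import (DEFAULT_CRO, DEFAULT_OTH, DEFAULT_ZOO,
                                 DEFAULT_ECOSYSTEM_STATE)

trajs = scenario_suite(DEFAULT_CRO, DEFAULT_OTH, DEFAULT_ZOO,
                       DEFAULT_ECOSYSTEM_STATE)
for label, traj in trajs.items():
    print(label, {pool: round(traj.final(pool), 3) for pool in traj.pools})
```

```
A {'Cro': 8494935.93, 'Oth': 81805.933, 'Zoo': 9.908}
B {'Cro': 1.045, 'Oth': 1.148, 'Zoo': 0.377}
C {'Cro': 7.216, 'Oth': 1.095, 'Zoo': 4.971}
```

At 100 nmol L⁻¹ of each nutrient (A) *Crocosphaera*'s high uptake maxima let
it outgrow both the other phytoplankton (~100-fold by day 10) and the
grazing pressure. At 1 nmol L⁻¹ without fixation (B) its high half-saturation
constants make it lose, slightly, to the high-affinity competitors. Enabling
the 0.31 d⁻¹ fixation floor (C) flips the outcome: the same nutrient-starved
diazotroph ends ~7× higher than without fixation.

The full demo pipeline — generate a synthetic experiment, estimate biomass,
build nitrogen budgets, simulate, and fit V_max^NH4 back from the noisy
tables:

```
crococompete run --config examples/demo.yaml --out-dir demo_run --seed 1
```

`demo_run/budget.csv` then contains, per treatment, the combined-N drawdown,
the summed biomass-N increment, their ratio (≈0.5–0.6: biomass explains about
half of the consumed N, the configured unexplained sink), and the percent of
the diazotroph's N demand met by fixation (≈5% in the control, ≈1.6% under
+NH₄⁺ where ammonium suppresses fixation). `demo_run/fit.json` holds the
multistart fit (vmax_nh4 ≈ 7.7 from 10%-noise data, truth 6.6).

Individual stages are also exposed as subcommands: `generate-data`,
`estimate-biomass`, `nitrogen-budget`, `simulate-incubation`,
`simulate-ecosystem`, `scenario-suite`, `fit`.

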