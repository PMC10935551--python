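# Methods

## Model structure

`hgtrace` couples a static trophic mass balance to a linear contaminant
fate model and a dietary exposure layer.

**Static balance.** A web is a list of functional groups (producers,
consumers, one detritus group) with biomass `B` (t km⁻² wet weight),
production/biomass `PB` (yr⁻¹), consumption/biomass `QB` (yr⁻¹, zero for
producers and detritus) and ecotrophic efficiency `EE ∈ [0, 1]`, plus a
diet matrix whose consumer rows sum to one. The balance residual for a
living group is `B·PB·EE − Σ predation − landings`; biomass accumulation
and migration are fixed at zero (closed system assumption). The detrital
budget is not part of the static balance; detritus enters the contaminant
model explicitly instead. Trophic levels solve `TL = 1 + DC·TL`, with
producers and detritus at TL 1.

**Contaminant dynamics.** Between release events the system is linear and
time-invariant over the state (water mass; one pool per group):

    dA_i/dt = u_i·C_w·B_i + α·Σ_j (A_j/B_j)·Q_ij − Σ_k (A_i/B_i)·Q_ki − e·A_i [− m_i·A_i]

with `Q` the static consumption matrix, `C_w` the water concentration and,
optionally, mortality routing `m_i = PB_i·(1−EE_i)` into the detritus
pool. Every loss term re-appears as a gain elsewhere (excretion and
unassimilated diet go back to the water), so the rate matrix is Metzler
with zero column sums and total mass is conserved by construction.

Key parameters, defaults and units:

| parameter | default | units | note |
|---|---|---|---|
| excretion rate `e` | 0.10 | yr⁻¹ | the modelled 10 % elimination read as a yearly first-order rate (no time base is stated with the percentage); configurable |
| assimilation `α` | 1.0 | — | prey-borne mercury fully retained; the 10 % loss is carried by `e` |
| direct uptake `u_i` | calibrated | L t⁻¹ yr⁻¹ | nonzero only for photosynthetic plankton, copepods, euphausiids; defined so the uptake flux per km² is `u·C_w·B` |
| detritus routing | on | — | keeps the detrital pool non-trivial while conserving mass; can be switched off to recover the bare uptake/diet/excretion form |
| background concentration | 0.57 | µg L⁻¹ | ICES-derived conservative value |
| background influx | 0.01 | t yr⁻¹ | CEFAS 2005–2014 average |
| geometry | 570 000 km², 95 m | | defines the mixed water volume (5.415 × 10¹⁶ L) |

## Numerical choices

Because the system is linear, propagation uses the **exact matrix
exponential** of the augmented (rate matrix | constant influx) system on a
fixed 1-year output grid, with release pulses added to the water pool
between segments. Compared with adaptive time stepping this is
deterministic, independent of step-size control, conserves mass to
machine precision (observed ≲ 10⁻¹³ relative over century runs) and can
never produce negative pools (the exponential of a Metzler matrix is
nonnegative).

**Equilibration.** With a constant influx the fully closed system has no
steady state — total mass grows linearly — so `run_to_equilibrium`
defaults to clamping the water concentration at its initial value and
solving the group steady state directly (LU solve with three steps of
iterative refinement, since pool magnitudes span many orders of
magnitude). This is the physically relevant regime: the background water
column holds ~3 × 10¹⁶ µg of mercury against yearly biotic fluxes many
orders smaller. The returned state is verified stationary to a maximum
relative pool change of 10⁻⁸ yr⁻¹. An unclamped mode integrates the full
system until the same criterion holds (horizon cap 10 000 yr) and raises
an error carrying the last state on non-convergence.

**Release events** are single pulses at the event year (the published
scenario analysis found no difference between single and setwise release);
`ExposureScenario.spread_release` provides the setwise variant for
sensitivity use. A pulse of mass `M` raises `C_w` by exactly `M/V`.

## Scenario constants

Preset release masses are the published constants — 0.07 t (ES B), 9.9 t
(ES C), 72.93 t (ES D), all at year 50 — and are deliberately **not**
recomputed from pipe geometry: annulus arithmetic on the stated
schedule-60 10″ pipe (OD 27.31 cm, wall 12.7 mm, steel 7850 kg m⁻³) gives
≈ 8.2 × 10⁴ kg steel per km, whereas the published masses imply
≈ 8.1 × 10⁵ kg km⁻¹, a tenfold gap that cannot be resolved from the text.
The geometry helpers (`steel_mass_per_km`, `pipeline_release_mass`) serve
custom scenarios. Similarly, ES C/D quote a post-release background of
4 × 10⁻⁶ t yr⁻¹ that is inconsistent with ES A's 0.01 t yr⁻¹; both are
carried as data (`background_influx` vs `post_release_influx`) rather than
silently reconciled.

## Validation conventions

* Muscle conversion is a pure multiplier on the whole-body concentration
  (fish 0.5, shrimp-like crustaceans 0.15, everything else 1.0). The
  source wording does not say whether a muscle mass fraction should divide
  the allocation; the alternative reading is available via the
  `convention` argument.
* NMB interpretation follows the published worked convention on both
  sides: factor `NMB + 1` (over) for `NMB ≥ 0` and `|NMB| + 1` (under)
  for `NMB < 0` — note this differs from the algebraic inverse
  `1/(NMB+1)` for negative bias (−0.2 → 1.2, not 1.25).
* Food standards: low trophic 0.5, high trophic 1.0 mg kg⁻¹ muscle. The
  source text states both orderings in different places; the methods-section
  reading (low = 0.5) is the default. Class assignment uses the group's
  `trophic_class`, set at generation time from trophic level (TL ≥ 4 →
  high; configurable).
* Dry-weight observations are converted at I/O with a per-row moisture
  fraction; everything internal is wet weight.

## Exposure layer

`EWI = AC·mehg·F·WI·AB·Frac / W`. The rendered source equation is
dimensionally resolvable only with body weight in the denominator, which
is how it is implemented. Defaults: absorption `AB = 0.79`,
bioaccessibility `F = 1.0` where no species value is given (conservative,
consistent with the worst-case stance of the assessment), methylmercury
fraction 0.95 of muscle total mercury for fish-level items (30 % / 15 %
conventions for zoo-/phytoplankton-class items are available per species).
Seafood is fixed to three food groups (oily fish, white fish, shellfish);
a group's weekly intake is divided evenly over its species, the North Sea
share (fish 0.21, shellfish 0.23) carries the scenario concentration and
the imported remainder carries the status-quo (ES A) concentration.
Thresholds: TWI 1.3 µg kg⁻¹ bw week⁻¹; HQ against the EPA weekly
reference dose 0.0007 mg kg⁻¹ week⁻¹ (7 × the daily 0.0001).

## Synthetic data: what it does and does not represent

The generator emulates the *shape* of the assessed system — 29 functional
groups with the named guilds (two phytoplankton groups, copepods,
euphausiids, benthos, shrimp-like crustaceans, the main commercial fish,
seabirds, seals, detritus), direct-uptake flags on the plankton groups,
muscle fractions and commercial flags — with invented parameter values:
biomass log-uniform in a window decreasing with trophic position within
0.01–50 t km⁻², P/B decreasing with position within 0.1–100 yr⁻¹,
Q/B = P/B/GE with GE ∈ [0.1, 0.3], Dirichlet diets over lower-ordered
groups at connectance 0.35. Consumer biomass is capped during generation
so no prey's EE can exceed 0.9, and EE is back-solved from realized
predation, so every emitted web balances exactly. All draws flow through
one explicit integer seed.

Uptake rates are calibrated rather than measured: `calibrate_uptake`
solves the linear system so flagged groups hit target equilibrium
concentrations, and `calibrate_to_background` rescales (by linearity) so
the maximum commercial muscle concentration at the 0.57 µg L⁻¹ background
equals 0.15 mg kg⁻¹ — below both food standards, consistent with the
regime in which the assessment operates (only the largest release pushes
any species above 0.2 mg kg⁻¹). Consumer profiles are synthetic
stand-ins: body weights near UK averages, NHS-regime intakes built from
the two-140-g-portions guidance, survey-regime intakes drawn strictly
below them component-wise.

Consequently, passing tests demonstrate the *method* — exact balance,
conservation, linearity, monotone scenario response, dominance of the
recommended-intake regime, sub-threshold baselines — not the published
concentrations of real North Sea species, which depend on the original
parameterization and uptake-rate derivations. Simulation sizes used in
the test suite (webs of 5–29 groups, century horizons, 100 random seeds
for the conservation sweep, 20 seeds × 100 studies for bias recovery)
were chosen as the smallest sizes at which these properties are
informative.

## Known limitations

* No sediment compartment, speciation kinetics, spatial dispersion or
  temporal biomass dynamics (biomasses stay at their balanced values);
  total mercury is tracked with uptake/retention tuned to methylmercury
  behaviour.
* With `α = 1` and a single elimination rate, trophic amplification per
  step is of order `QB/e`; realistic absolute concentrations therefore
  rest entirely on the uptake-rate calibration, not on mechanistic
  uptake physiology.
* The excretion percentage is interpreted as a yearly rate; if the source
  intended a different time base every absolute concentration scales
  accordingly (patterns and ratios are unaffected at calibrated
  baselines).
* No Monte-Carlo exposure assessment and no cooking-loss modelling.
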