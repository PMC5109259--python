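# Methods

## Scope and model structure

`rpra` implements a regional probabilistic (Monte Carlo) non-carcinogenic
risk assessment for heavy metals across multiple environmental media and
land uses. Seven exposure scenarios are built in: four surface-soil land
uses (riverbank vegetable plots RVS, riverbank green spaces RGS, private
vegetable plots PVS, public green spaces PGS), groundwater predicted by
leaching from the 0–100 cm soil profile, surface water, and river
sediments. Each scenario pairs a medium with its most sensitive receptor
and the routes that receptor's behaviour implies:

| scenario | receptor | routes |
|---|---|---|
| RVS, PVS | farmers | soil ingestion, dermal, inhalation, vegetable ingestion |
| RGS, PGS | residents outdoors | soil ingestion, dermal, inhalation |
| groundwater | residents drinking | water ingestion only |
| surface water | residents drinking / swimming | water ingestion, dermal |
| sediment | swimmers | sediment ingestion, dermal |

Hazard quotients are chronic daily intake over route-specific chronic
reference dose; the scenario total (THQ) sums over routes and the eight
metals As, Hg, Cd, Zn, Pb, Cu, Cr, Ni. Carcinogenic risk is out of scope
(validated slope factors are missing for most of these metals), as are
speciation/bioaccessibility adjustments, age-stratified receptors and any
spatial interpolation.

## Route equations and unit conventions

All intake equations are standard chronic-daily-intake forms; the unit
chain is explicit everywhere (10⁻⁶ kg/mg for ingested solids, 10⁻³ mg/µg
for dissolved metals with water intake in L/d, 10⁴ cm²/m² for skin areas,
10⁻⁶ for µg/L → mg/cm³ in the dermal-water route). A dimensional-audit
test multiplies symbolic unit exponents through every route and asserts
exact cancellation.

Three modelling choices deserve emphasis:

* **Groundwater leaching.** `C_gw = 10³ · C_ts / ((K_d + θ_w/ρ_b) · DF)` —
  equilibrium soil–water partitioning of the 0–100 cm profile concentration
  with a dilution factor for transport to the aquifer. This is the standard
  soil-to-groundwater screening form; its plausibility is anchored by the
  survey observation that predicted groundwater concentrations are close to
  the measured surface-water concentrations, and the default K_d values are
  chosen to respect exactly that diagnostic (see below).
* **Vegetable ingestion.** The plant uptake factor is defined on dry plant
  mass while intake rates are fresh weight, so the model converts with
  (1 − θ_v), θ_v being the vegetable water content (~0.90). HQ is linear in
  PUF and in soil concentration.
* **Dermal water contact.** The permeability constant K_p (cm/h) acts over
  an exposure time per event, so an explicit ET (h/event) parameter is
  required dimensionally, with swimming frequency EF_sw in events/yr.
  Soil/sediment adherence is likewise per contact event, with exposure
  days acting as events.

Averaging time follows the non-carcinogenic convention AT = ED × 365 d
(overridable). Inhalation combines dust and vapour additively,
(1/PEF + 1/VF), the vapour term existing only for elemental Hg
(VF = 32,376.4 m³/kg); with PEF = 1.36×10⁹ m³/kg the Hg vapour term
dominates the inhalation route by ~4 orders of magnitude.

## Monte Carlo protocol

Each scenario draws 10,000 iterations (configurable, ≥ 100). Parameter
marginals are point, truncated lognormal, or triangular. Lognormals are
parameterized by *arithmetic* mean and sd via the moment identities
µ_log = ln(m²/√(m²+s²)), σ²_log = ln(1+s²/m²); truncation is by rejection
with an acceptance-rate guard (< 1% acceptance is reported as an infeasible
specification naming the parameter).

Dependence is imposed by Iman–Conover rank-correlation reordering: columns
are re-paired to match the ranks of correlated van der Waerden scores
(target Spearman ρ mapped to normal-score correlation by 2·sin(πρ/6)), so
every marginal is preserved exactly and any declared pair reaches its
target within ±0.05 at n = 10,000. Declared pairs and defaults:

* body weight ↔ skin surface areas: +0.7 (both areas also carry their
  implied mutual correlation 0.7² ≈ 0.49; without it the three-way
  structure is not positive semi-definite);
* plant uptake factor ↔ soil–water partition coefficient, per metal: −0.7
  (stronger sorption leaves less metal available for uptake);
* co-sourced metals within a generated site (As, Cd, Zn, Pb, Cu): +0.5.

The magnitudes are modelling defaults — the dependence pairs are part of
the study design, their strengths are not published — and are configurable.

Reproducibility: a single top-level seed is combined with each parameter's
name (BLAKE2-hashed) to derive an independent stream, so identical
(specs, correlations, seed, n) give bit-identical draws and adding a
parameter never perturbs the others.

## Default parameter tables

The exposure-parameter table (`data/exposure_parameters_default.csv`) and
metal-property table (`data/metal_properties_default.csv`) are
literature-assembled stand-ins for an adult receptor, in the style of the
Chinese Exposure Factors Handbook and USEPA exposure-factor and RAGS/IRIS
compilations: 2 L/d drinking water, 0.3 kg/d fresh vegetables, 70 mg/d
incidental soil ingestion, 15 m³/d inhalation, 60 kg body weight, 24 yr
exposure duration, 350 d/yr indoor and 225 d/yr outdoor frequency, ~30
swimming events/yr. Reference doses are the standard oral values (As
3×10⁻⁴, Cd 1×10⁻³, Cr 3×10⁻³ mg/kg/d, …) with dermal values scaled by
gastrointestinal absorption and inhalation values from reference
concentrations where they differ (Hg 8.57×10⁻⁵ mg/kg/d).

Two metal-specific transfer factors have no single literature value and
were fixed once as follows:

* **Plant uptake factors** (dry weight, leafy vegetables) sit within
  published ranges (e.g. Cd 0.36, Zn 0.11, As 0.004) and jointly reproduce
  the qualitative per-metal contribution pattern of vegetable-route risk
  (As and Cd dominant, then Pb and Cr).
* **Soil–water partition coefficients** (hundreds to thousands of L/kg)
  are set so that the *mean* predicted groundwater concentration of each
  metal matches the measured surface-water mean — the diagnostic the survey
  itself reports. Because K_d and DF enter as 1/((K_d+θ_w/ρ_b)·DF) and both
  are strongly right-skewed, this calibration is done against the full
  Monte Carlo expectation, not the central values.

Both tables are overridable per run; the run manifest records the SHA-256
digest of whichever tables were used.

## Synthetic field data

The generator reproduces the survey's structure: per-stratum site counts
(RVS 7, RGS 13, PVS 11, PGS 20, profiles 6, water 10, sediment 10),
stratum × metal truncated-lognormal concentrations, within-site rank
correlation 0.5 among the co-sourced metals, and a uniform(5.5, 7.5) soil
pH column that is carried but unused (no pH–K_d relationship is modelled).

Because a survey summary describes data that lie inside the observed
[min, max], the generator solves for underlying lognormal parameters whose
*truncated* mean equals the declared mean exactly (1-D root in the
log-location using closed-form truncated moments) and whose truncated sd is
as close as possible to the declared sd. For tight observed ranges the
declared sd is unattainable — no distribution on [lo, hi] with mean m has
sd above √((m−lo)(hi−m)) — so realized spreads can fall short by tens of
percent there; realized means match to Monte Carlo error.

What passing tests on generated data do and do not show: they exercise the
full pipeline against data with the survey's marginal statistics and a
plausible co-contamination structure, but real surveys have spatial
autocorrelation, depth structure, analytical error and non-lognormal tails
that the generator does not emulate.

## Risk characterization and sensitivity

Percentiles use linear interpolation between order statistics (the common
default; the convention is stated because reported percentiles are
convention-dependent). CV is sd/mean in percent; exceedance probability is
the strict fraction of iterations above HQ = 1; contribution shares are
computed on means so they are exactly additive to 100%. The 95th
percentile of each scenario THQ is reported with a bootstrap standard
error (200 resamples) to quantify cross-run Monte Carlo scatter.

Sensitivity ranking uses Spearman rank correlation of each sampled input
against THQ (robust to lognormal skew, invariant to monotone transforms),
two-tailed significance at α = 0.01 without multiplicity correction;
Pearson is available as an option and the method used is recorded in the
output metadata. Constant (point) inputs are excluded. Note that
correlated inputs share rank: skin areas inherit part of body weight's
(negative) association.

## Problem sizes and determinism

The shipped defaults — 10,000 iterations per scenario, seven scenarios,
~50 sampled parameters each — run in about one second per study on a
single CPU. The acceptance script uses the same sizes. The scenario-order
robustness test runs the full study over 20 seeds; generated-data runs add
the truncated-moment matching step (cached per summary).

## Known limitations

* The exposure-parameter and metal-property defaults are assembled
  stand-ins, not a site-specific transcription; absolute HQ levels carry
  that ambiguity even though the scenario ordering and route structure are
  robust to it.
* The leaching model is an equilibrium screening form; kinetics,
  preferential flow and pH dependence of K_d are not modelled (pH is
  carried in generated data but unused).
* Dermal uptake of metals from water is small under any plausible K_p, so
  that route is effectively a reporting detail.
* THQ sums hazard quotients across metals and routes, the conventional
  additivity assumption; it ignores toxicological interaction.
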