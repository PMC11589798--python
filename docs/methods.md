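# Methods

`vpop` couples three submodels — childhood energy balance, adult disease
progression, and lifetime costing — behind a counterfactual scenario engine.
This note records the model equations, the assumptions behind them, the
parameter choices that matter, and what the synthetic inputs do and do not
emulate.

## Synthetic population

The cohort represents US children aged 6–17 in four sex × age-group strata.
Stratum sizes are the Census counts scaled by a user fraction and rounded by
largest-remainder apportionment (floors plus leftover units to the largest
fractional remainders, ties broken in fixed stratum order), so scaled totals
are conserved and full scale reproduces the national counts exactly. Ages
are uniform within each 6-year band, which is all the banded counts support.

Body composition is drawn from truncated-normal (positive) marginals with
the published stratum mean/SD for fat-free and fat mass. Two departures from
a literal reading of those inputs:

* **Age scaling.** A single stratum mean across a six-year band would give
  6-year-olds teenage masses. The mean and SD are scaled by the growth
  reference's median body mass at the agent's age, normalised so the
  stratum-level marginal mean and SD still equal the published values
  (`body_composition.age_scaling`, on by default).
* **Prevalence calibration.** Published marginals plus median heights do not
  reproduce the published overweight/obesity prevalence, and for one stratum
  (female 6–11, FFM 32.42 ± 10.82 kg) no adjustment of fat mass alone can:
  sampled fat-free mass exceeds the 95th-percentile *total* mass for a large
  share of agents. Calibration therefore applies a monotone affine map to
  each stratum's BMI-for-age z-scores — feasible and exact because the youth
  category cut points (85th/95th percentile) are constants on the z scale —
  anchored at the empirical quantiles matching the two prevalence targets.
  The implied mass change is taken from fat mass first and spills into
  fat-free mass only at the physiologic floors (0.5 kg fat, 5 kg fat-free).
  The map is rank-preserving away from the floors and idempotent up to
  quantile-interpolation error. The calibrated cohort matches all eight
  stratum targets to well under half a percentage point at 10⁵ agents.

The fat row of the published inputs ("fat tissue and fat mass ratio") has
ambiguous units; the default reads it as fat mass in kg, with a config flag
(`fat_mass_interpretation: ratio`) to read it as a fat/fat-free ratio
instead. Sports participation is Bernoulli with the sex-specific
probability; the underlying uniform is stored per agent so counterfactual
participation levels re-evaluate the same draw (coupled across arms). One
documented inconsistency in the source material — running text giving
female participation as 35.4% where the input table prints 34.5% — is
resolved in favour of the table.

What the generator does *not* emulate: joint FFM–FM correlation beyond
stratum means (only marginals are published), measured heights (heights are
the reference median at the agent's age, so BMI variation is carried
entirely by mass), race/ethnicity and socioeconomic structure, and
secular trends. Passing tests show internal consistency with the published
stratum-level inputs, not person-level survey realism.

## Growth reference

BMI-for-age is standardised with an LMS table (Box-Cox power L, median M,
coefficient of variation S per sex at quarter-year steps, ages 2–20) plus
median height by age: `z = ((BMI/M)^L − 1)/(L·S)`. The packaged table is
**synthetic** — smooth CDC-like curves generated by
`scripts/make_growth_reference.py` — chosen so that the youth 85th/95th
percentile cuts at age 18 land near the adult BMI 25/30 thresholds (they
map to 25.3 and ≈29), making the hand-off from percentile-based youth
classification to absolute adult classification nearly seamless. The file
format is the contract: a genuine LMS reference drops in via the
`growth_reference` config key. Youths are classified overweight at the
85th–94th and obese at the ≥95th BMI-for-age percentile; adults at BMI
25/30.

## Childhood energy balance

One-day timesteps from entry age to 18.

* **Weekly behaviour.** Each week an agent draws a mean number of active
  days from N(μ, σ) truncated to [0, 7], stochastically rounded
  (floor + Bernoulli on the fraction) so the long-run weekly mean equals the
  drawn value; an intensity from N(MET mean, MET SD) truncated at 1; and,
  for sports participants, a sports intensity from a triangular distribution
  over the published (min, mean, max) — the three numbers the source
  provides — applied to the sex-specific weekly MVPA block, spread evenly
  over seven days and strictly additive to non-sport PA. Draws are redrawn
  every week with no autocorrelation (none is documented). Active days give
  the configured active-day minutes (default 60); other days give the
  non-PA-day minutes (default 30, sensitivity 0–45), at the same drawn
  intensity.
* **Expenditure.** Net-of-rest activity cost is `(MET − 1) · c · mass ·
  minutes`, c = 3.5/200 kcal·kg⁻¹·min⁻¹; resting expenditure is linear in
  FFM and FM (Katch-McArdle-type coefficients 370 + 21.6·FFM + 3.2·FM
  kcal/day) plus a flat 60 kcal/day growth-energy term for minors. The
  (MET − 1) convention keeps resting expenditure out of the activity term,
  so nothing is double-counted.
* **Mass update.** Surplus S partitions with the Forbes fat-free share
  `p = C/(C + FM)` (C = 10.4 kg) and converts at tissue energy densities
  ρ_F = 9441 and ρ_L = 1807 kcal/kg. Energy is conserved exactly —
  `ρ_F·ΔFM + ρ_L·ΔFFM = ΣS` to < 10⁻⁶ kcal over 1000-day windows — unless a
  physiologic floor engages (floored agents are flagged). Constants come
  from the standard energy-balance literature and are config-editable.
* **Maintenance intake.** Each agent eats the amount that holds its
  BMI-for-age *percentile* constant along the reference given its baseline
  expected activity (analytic truncated-normal/triangular means, so the
  expectation matches the stochastic draws exactly). The intake path is
  computed in closed form — the daily surplus needed to track the
  percentile-constant mass trajectory, with the weekly target spread over
  the week's days — recorded per week, and **frozen**: scenario runs reuse
  the baseline schedule, which is precisely how added activity produces a
  caloric deficit and weight loss. A constant-intake variant solved by
  bisection over an arbitrary horizon (`maintenance_intake`, ±1 kcal/day,
  percentile tolerance 0.005) implements the same contract for single
  horizons and is cross-checked against the path in the tests. Under the
  frozen schedule, stratum mean percentiles drift < 1 percentile point per
  simulated year on 10⁴-agent runs; the residual drift comes from
  activity-variance asymmetry and floor clipping.

Adult BMI is carried forward from the age-18 state; whether adults' weight
evolves afterwards is not specified by the study design this follows, so
the age-18 weight category is the flagged, explicit input to the disease
model.

## Adult disease model

Annual cycles from 18 to a maximum age (default 100). Conditions are
semi-independent hazard flags rather than a mutually exclusive state
machine because cases are counted additively across conditions (they can
co-occur). Each year, in fixed order (stroke, CHD, diabetes, neuropathy,
retinopathy, nephropathy, cancer — complications after diabetes and gated
on it): onset with probability `incidence(age band, sex) × RR(category)`,
probabilities validated ≤ 1; then mortality as independent draws of
background risk (Gompertz, forced to 1 at the maximum age) and
per-active-condition excess hazards — equivalent to `1 − Π(1 − qᵢ)` — with
cause attributed to the first firing hazard. Death absorbs. Every
agent-year consumes a fixed number of uniforms, so paired runs stay
aligned: with all RRs at 1 the weight category provably has no effect, and
raising an RR adds onsets agent by agent when lifespans are held equal.

The shipped incidence/RR/mortality values are placeholders with US-like
magnitudes, clearly labelled in the config; the tabular interface
(condition, age band, sex, incidence, RRs, excess mortality) is designed so
calibrated tables replace them without code changes.

## Economics

Year by year from simulation entry to death, discounted to entry at 3%:
QALYs weighted by the product of active-condition utilities (multiplicative
comorbidity — unspecified upstream, chosen as the conservative standard that
keeps weights in [0, 1]); direct medical costs as the sum of
active-condition annual costs; presenteeism as
`daily wage × (1 − combined utility) × 365` for every agent regardless of
age or employment. Conditions persist from onset to death. Childhood years
accrue healthy-utility QALYs and no disease costs (the disease model starts
at 18), with fractional first years pro-rated; childhood QALYs are
discounted to the same entry reference. Within a cycle, onsets are
evaluated before accrual and mortality after it, so the onset year is lived
and costed — a half-cycle convention, stated rather than hidden. The
societal perspective equals third-party (direct) plus productivity exactly,
per agent, by construction and by test.

## Scenario engine and inference

`apply_disparity_reduction` interpolates female *means* toward male values
(`female + r(male − female)`) on the selected dimensions; male parameters
and female variability are untouched; r = 0 is the identity. The
non-PA-day-minutes override applies to both sexes and both arms — it is a
world-state sensitivity, not an intervention. Baseline and scenario share
one cohort and identical random streams: all stochastic draws go through
inverse CDFs on a fixed number of uniforms per agent-week (activity) and
agent-year (disease), which makes paired deltas free of cohort-sampling
noise and outcomes monotone in location parameters agent by agent — the
mechanism-direction tests exploit exactly this coupling.

Outcomes follow the study's accounting: overweight/obesity cases averted at
18 and all downstream outcomes are counted in female agents (the scenarios
act on females); the prevalence change is all-population; rows are broken
out by entry age group. Replicate deltas are scaled to national counts by
1/scale; the 95% CI is a percentile bootstrap of the replicate mean (2000
resamples, fixed internal seed). A plain percentile band across replicates
was rejected because it is a dispersion band: it covers the true mean
essentially always, whereas the bootstrap-of-the-mean band has near-nominal
coverage (≈93% at 20–25 replicates in the coverage test).

Seeds: a run seed spawns cohort, childhood and disease streams through a
`default_rng` integer split; every CLI run writes a manifest recording seed,
scale, replicates and scenario.

## Problem sizes and numerical choices

Default driver runs use 4,150-agent replicates (scale 5 × 10⁻⁴, 10
replicates) for the full pipeline; the heavier verification runs use 10⁴
agents × 20 replicates (childhood stage) and 10⁵ agents for calibration
recovery — sizes chosen so the whole verification suite completes on a
single CPU while keeping Monte-Carlo error well inside the asserted
tolerances. The day-stepping kernels are numba-compiled; cohort state is
float64 throughout, which the exact energy-conservation checks rely on.
Degenerate inputs are handled explicitly: zero SDs collapse draws to the
(clipped) mean, zero prevalence targets shift whole strata below the
overweight cut, infeasible targets (≥100% combined) raise a calibration
error, and maintenance-intake bisection reports bracket failures with the
offending agents.

## Known limitations

* Disease, cost and utility tables are uncalibrated placeholders; absolute
  disease counts, QALYs and dollars are pipeline illustrations until real
  tables are supplied. The childhood weight outcomes (cases averted,
  prevalence changes) depend only on the published behavioural and
  anthropometric inputs and the energy-balance model.
* The growth reference is synthetic; swap in a real LMS table for
  population-grade classification.
* Heights are deterministic medians; within-stratum BMI variance is carried
  by mass alone.
* No seasonality, day-of-week structure, activity autocorrelation, disease
  remission, treatment effects, or adult weight dynamics.
* Sex is binary male/female, following the available input strata;
  nonbinary and transgender youth are not represented.
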