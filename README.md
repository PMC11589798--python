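# vpop — health and economic outcomes of closing sex gaps in youth physical activity

US girls are less physically active than boys: fewer days per week with at
least 60 minutes of physical activity (PA), lower average intensity, and
lower sports participation. `vpop` is an agent-based microsimulation that
asks what would happen if those gaps were reduced or eliminated. It is
aimed at modellers and health economists who want a transparent, testable
implementation of the full causal chain:

1. **Synthetic population** — all four US Census sex × age-group (6–11,
   12–17) strata, body composition (fat-free mass *FFM*, fat mass *FM*)
   drawn from survey-derived marginals and calibrated so each stratum's
   classified overweight/obesity prevalence matches national targets.
2. **Childhood energy balance (1-day steps to age 18)** — each week an
   agent draws active days *D* ~ N(μ, σ) truncated to [0, 7] and intensity
   *MET*; activity burns `(MET − 1) · c · mass · minutes` net of rest
   (c = 3.5/200 kcal·kg⁻¹·min⁻¹). Daily surplus `S = intake − REE − activity`
   moves tissue mass via a Forbes-style partition `p = C/(C + FM)`:
   `ΔFFM = p·S/ρ_L`, `ΔFM = (1−p)·S/ρ_F` (ρ_F = 9441, ρ_L = 1807 kcal/kg).
   Intake follows the *maintenance rule*: the amount that keeps the agent's
   BMI-for-age percentile constant given **baseline** expected activity —
   and stays frozen under scenarios, so extra activity becomes weight loss.
3. **Adult Markov model (1-year steps, 18 → 100)** — stroke, coronary heart
   disease, type 2 diabetes and its complications (neuropathy, retinopathy,
   nephropathy), and cancers: annual onset with probability
   `incidence(age, sex) × RR(weight category at 18)`, plus background and
   per-condition excess mortality. Shipped transition/cost/utility tables
   are labelled placeholders and are user-replaceable.
4. **Economics** — discounted (3%/yr) QALYs, direct medical costs
   (third-party payer) and presenteeism productivity losses
   (`daily wage × (1 − utility) × days`); societal = direct + productivity.
5. **Scenario engine** — moves female parameters toward male levels by a
   fraction r (`female + r·(male − female)`) on any of: PA days, PA
   intensity, PA minutes, sports participation, sports MVPA. Baseline and
   counterfactual run on the same cohort with common random numbers, so
   paired deltas isolate the intervention; replicate means get
   percentile-bootstrap 95% CIs and are scaled to national counts.

## Worked example

```bash
python analysis/02_pa_days_grid.py
```

runs the paired grid (4,150 agents per replicate, 10 replicates, full
childhood + adult + economics pipeline) for 25–100% reductions of the
PA-days disparity and prints:

```
eliminating the PA-days disparity (fraction 1.0):
  overweight/obesity cases averted (female, national): 26,400
  all-population prevalence change: 0.318 pp
  weight-related disease cases averted: 9,400
  societal savings: $1,820.5M (direct $701.3M + productivity $1,119.2M)
cases averted by reduction fraction: {0.25: 8200, 0.5: 13800, 0.75: 20000, 1.0: 26400}
```

Reading it: raising the female mean from 3.97→4.16 (ages 6–11) and
3.07→3.68 (ages 12–17) active days/week, with intake frozen at baseline,
prevents ≈26k national female overweight/obesity cases by age 18 and drops
all-population prevalence by ≈0.32 percentage points; the effect grows
near-linearly in the reduction fraction. Downstream disease counts and
dollar figures depend on the placeholder transition/cost tables and should
be read as illustrating the pipeline, not as calibrated estimates.

The other drivers build and check the calibrated cohort
(`01_build_cohort.py`), run the sports-participation grid
(`03_sports_participation_grid.py`), and show that the disparity's impact
shrinks as everyone gets more activity on non-PA days
(`04_nonpa_minutes_sensitivity.py`). Each writes its table under
`results/`.

There is also a CLI:

```bash
vpop params dump-defaults          # the packaged parameter file, with sources
vpop params validate my.yaml       # check a (partial) override file
vpop cohort build --scale 1e-3 --seed 1 --out cohort.csv
vpop run --scenario pa_days --fraction 1.0 --scale 5e-4 --replicates 10 \
         --seed 42 --out results/run1
```

## Layout

```
src/vpop/          the library: params, growth, population, activity,
                   metabolism, disease, economics, experiments, cli
src/vpop/data/     packaged defaults (YAML, with per-block sources) and the
                   synthetic LMS growth reference (CSV; a real LMS table in
                   the same format drops in via the growth_reference key)
analysis/          numbered narrative drivers writing tables to results/
docs/methods.md    model description, assumptions, parameter choices, limits
tests/             pytest suite (unit, property and acceptance tests)
```
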