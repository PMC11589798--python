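# Packaged default parameters for the vpop microsimulation.
#
# Behavioral and anthropometric blocks carry the published national input
# values (US Census population counts; NSCH 2016-2020 activity days;
# NHANES 2017-2020 body composition and overweight/obesity prevalence;
# observational sports-participation surveys). Disease-progression and
# cost/utility blocks are PLACEHOLDERS with literature-plausible magnitudes:
# calibrate or replace them before drawing quantitative conclusions.
# Every block records its source in a "source" string.

demography:
  source: "US Census 2022, population counts by sex and age group"
  counts:
    male:
      "6-11": 2078664
      "12-17": 2161455
    female:
      "6-11": 1992402
      "12-17": 2066832

activity:
  source: >-
    National Survey of Children's Health 2016-2020 (weighted mean days/week
    with >=60 min physical activity); Harrell et al. 2003 (MET intensity)
  active_days:
    male:
      "6-11": {mean: 4.16, sd: 0.08}
      "12-17": {mean: 3.68, sd: 0.08}
    female:
      "6-11": {mean: 3.97, sd: 0.07}
      "12-17": {mean: 3.07, sd: 0.07}
  intensity_met:
    male: {mean: 5.3, sd: 1.6}
    female: {mean: 4.3, sd: 1.56}
  active_day_minutes:
    male: 60.0
    female: 60.0
  nonactive_day_minutes:   # sensitivity range 0-45
    male: 30.0
    female: 30.0

sports:
  source: >-
    Project Play 2023 (participation %); Kanters et al. / Sports & Fitness
    Industry Association 2024 (MVPA min/week and MET intensity by sport)
  participation:
    male: 0.402
    female: 0.345
  mvpa_min_per_week:
    male: 418.49
    female: 320.59
  intensity_met:
    male: {mean: 3.95, min: 3.02, max: 4.84}
    female: {mean: 3.55, min: 2.41, max: 4.35}

body_composition:
  source: "NHANES 2017-2020, stratum mean (SD) across population"
  # The published fat row is headed "fat tissue and fat mass ratio"; units are
  # ambiguous. Default interpretation: fat mass in kg ('kg'); set to 'ratio'
  # to read the values as fat/fat-free ratios instead.
  fat_mass_interpretation: kg
  # Scale the stratum mean/SD with the reference median body mass across the
  # age band (normalised so the stratum marginal mean/SD are unchanged).
  age_scaling: true
  fat_free_mass_kg:
    male:
      "6-11": {mean: 26.12, sd: 6.45}
      "12-17": {mean: 52.94, sd: 11.41}
    female:
      "6-11": {mean: 32.42, sd: 10.82}
      "12-17": {mean: 40.92, sd: 6.73}
  fat_mass:
    male:
      "6-11": {mean: 7.35, sd: 3.66}
      "12-17": {mean: 13.11, sd: 5.18}
    female:
      "6-11": {mean: 15.20, sd: 7.84}
      "12-17": {mean: 20.21, sd: 6.90}

prevalence_targets:
  source: "NHANES 2017-2020, mean (95% CI), percent"
  overweight_pct:
    male:
      "6-11": {mean: 12.79, ci: [9.83, 15.74]}
      "12-17": {mean: 14.45, ci: [10.86, 18.03]}
    female:
      "6-11": {mean: 13.58, ci: [10.35, 16.80]}
      "12-17": {mean: 18.21, ci: [14.39, 22.03]}
  obesity_pct:
    male:
      "6-11": {mean: 23.72, ci: [19.79, 27.66]}
      "12-17": {mean: 21.77, ci: [17.95, 25.58]}
    female:
      "6-11": {mean: 17.58, ci: [13.72, 20.98]}
      "12-17": {mean: 20.23, ci: [16.54, 23.91]}

metabolic:
  source: >-
    Energy densities and fat-free partition constant from the Hall/Forbes
    energy-balance literature (9441 kcal/kg fat, 1807 kcal/kg lean, Forbes
    C ~ 10.4 kg); resting-expenditure coefficients are Katch-McArdle-type
    lean-mass regressions; 1 MET = 3.5 ml O2/kg/min ~ 0.0175 kcal/kg/min.
  rho_fat_kcal_per_kg: 9441.0
  rho_lean_kcal_per_kg: 1807.0
  forbes_c_kg: 10.4
  kcal_per_kg_met_min: 0.0175
  resting:
    male: {intercept_kcal: 370.0, per_kg_ffm: 21.6, per_kg_fm: 3.2}
    female: {intercept_kcal: 370.0, per_kg_ffm: 21.6, per_kg_fm: 3.2}
  growth_kcal_per_day_minor: 60.0
  fat_mass_floor_kg: 0.5
  fat_free_mass_floor_kg: 5.0

growth_reference: null   # path to an LMS CSV; null = packaged synthetic table

disease:
  source: >-
    PLACEHOLDER — calibrate or replace. Annual transition probabilities with
    US-registry-like magnitudes; the published model's supplementary
    transition tables are not redistributed here.
  max_age: 100
  background_mortality:
    source: "PLACEHOLDER Gompertz fit; forced to 1 at max_age"
    gompertz_a: 9.6e-05   # annual probability at age 0 scale
    gompertz_b: 0.078     # log-hazard slope per year of age
  # relative risks are indexed by adult weight category at age 18
  conditions:
    stroke:
      incidence:
        male: {"18-39": 0.0002, "40-59": 0.002, "60-79": 0.008, "80+": 0.020}
        female: {"18-39": 0.0002, "40-59": 0.0018, "60-79": 0.0075, "80+": 0.020}
      rr: {healthy: 1.0, overweight: 1.15, obesity: 1.45}
      excess_mortality: 0.05
    chd:
      incidence:
        male: {"18-39": 0.0005, "40-59": 0.005, "60-79": 0.013, "80+": 0.022}
        female: {"18-39": 0.0004, "40-59": 0.0035, "60-79": 0.011, "80+": 0.021}
      rr: {healthy: 1.0, overweight: 1.25, obesity: 1.60}
      excess_mortality: 0.04
    diabetes:
      incidence:
        male: {"18-39": 0.002, "40-59": 0.008, "60-79": 0.012, "80+": 0.008}
        female: {"18-39": 0.002, "40-59": 0.007, "60-79": 0.011, "80+": 0.008}
      rr: {healthy: 1.0, overweight: 1.60, obesity: 2.60}
      excess_mortality: 0.010
    neuropathy:
      requires: diabetes
      incidence:
        male: {"18-39": 0.030, "40-59": 0.030, "60-79": 0.030, "80+": 0.030}
        female: {"18-39": 0.030, "40-59": 0.030, "60-79": 0.030, "80+": 0.030}
      rr: {healthy: 1.0, overweight: 1.0, obesity: 1.0}
      excess_mortality: 0.005
    retinopathy:
      requires: diabetes
      incidence:
        male: {"18-39": 0.025, "40-59": 0.025, "60-79": 0.025, "80+": 0.025}
        female: {"18-39": 0.025, "40-59": 0.025, "60-79": 0.025, "80+": 0.025}
      rr: {healthy: 1.0, overweight: 1.0, obesity: 1.0}
      excess_mortality: 0.002
    nephropathy:
      requires: diabetes
      incidence:
        male: {"18-39": 0.020, "40-59": 0.020, "60-79": 0.020, "80+": 0.020}
        female: {"18-39": 0.020, "40-59": 0.020, "60-79": 0.020, "80+": 0.020}
      rr: {healthy: 1.0, overweight: 1.0, obesity: 1.0}
      excess_mortality: 0.008
    cancer:
      incidence:
        male: {"18-39": 0.001, "40-59": 0.006, "60-79": 0.016, "80+": 0.022}
        female: {"18-39": 0.001, "40-59": 0.006, "60-79": 0.014, "80+": 0.019}
      rr: {healthy: 1.0, overweight: 1.10, obesity: 1.30}
      excess_mortality: 0.08

economics:
  source: >-
    PLACEHOLDER cost/utility magnitudes in 2024 USD — calibrate or replace.
    Discount rate and presenteeism formula follow standard health-economic
    practice (3% net present value; daily wage x (1 - utility) x days).
  discount_rate: 0.03
  daily_wage_usd: 300.0
  healthy_utility: 1.0
  perspective: societal   # or third_party
  conditions:
    stroke: {annual_cost_usd: 15000.0, utility: 0.70}
    chd: {annual_cost_usd: 12000.0, utility: 0.80}
    diabetes: {annual_cost_usd: 10000.0, utility: 0.85}
    neuropathy: {annual_cost_usd: 3000.0, utility: 0.90}
    retinopathy: {annual_cost_usd: 2000.0, utility: 0.90}
    nephropathy: {annual_cost_usd: 8000.0, utility: 0.80}
    cancer: {annual_cost_usd: 40000.0, utility: 0.75}
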