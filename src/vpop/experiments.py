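"""Disparity-reduction scenarios, paired replicates, and outcome summaries.

A scenario shrinks the female-male gap in one or more behaviour dimensions
by a fraction ``r``: each selected female parameter moves to
``female + r * (male - female)`` (r = 1 eliminates the disparity, r = 0 is
the identity; male parameters are never touched). Baseline and scenario are
run on the *same* cohort with identical random streams (common random
numbers), so per-agent paired differences isolate the intervention effect;
replicate means and percentile 95% CIs are scaled to national counts.

Reported outcomes follow the study's accounting: overweight/obesity cases
averted by age 18 and all downstream outcomes (disease cases and deaths
averted, QALYs and life-years saved, direct-medical and productivity
savings) are counted in female agents — the scenarios act on females — while
the prevalence change is reported for the whole population. Rows are broken
out by entry age group and in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityProfile, build_profile
from .disease import BACKGROUND, AdultResult, compile_disease, simulate_adult_cohort
from .economics import LedgerArrays, accrue_cohort
from .growth import GrowthReference, load_growth_reference
from .metabolism import ChildhoodResult, expected_activity_per_kg, \
    maintenance_intake_path, simulate_childhood_cohort
from .params import AGE_GROUPS, ModelParams
from .population import Cohort, build_cohort

DIMENSIONS = ("pa_days", "pa_intensity", "pa_minutes", "sports_participation",
              "sports_mvpa")
#: weight-related conditions reported individually in the outcome tables
REPORTED_CONDITIONS = ("cancer", "chd", "diabetes", "stroke")
#: outcomes that are rates (not scaled to national counts)
RATE_OUTCOMES = frozenset({"prevalence_change_pp"})

GROUP_ROWS = AGE_GROUPS + ("total",)


@dataclass(frozen=True)
class ScenarioSpec:
    """Which disparity dimensions to shrink, and by how much.

    ``nonpa_minutes`` optionally overrides the minutes of PA everyone gets
    on non-PA days (a sensitivity setting that applies to baseline and
    scenario alike).
    """

    dimensions: tuple
    fraction: float
    nonpa_minutes: float | None = None

    def __post_init__(self):
        dims = tuple(self.dimensions) if not isinstance(self.dimensions, str) \
            else (self.dimensions,)
        object.__setattr__(self, "dimensions", dims)
        if not dims:
            raise ValueError("scenario needs at least one dimension")
        unknown = set(dims) - set(DIMENSIONS)
        if unknown:
            raise ValueError(f"unknown dimensions {sorted(unknown)}; "
                             f"valid: {DIMENSIONS}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"reduction fraction must be in [0, 1], got {self.fraction}")


def with_nonpa_minutes(params: ModelParams, minutes: float) -> ModelParams:
    """Set everyone's non-PA-day minutes (sensitivity range 0-45)."""
    out = params.copy()
    for s in ("male", "female"):
        out.activity.nonactive_day_minutes[s] = float(minutes)
    return out


def apply_disparity_reduction(params: ModelParams, spec: ScenarioSpec) -> ModelParams:
    """Interpolate female behaviour parameters toward male levels.

    Returns a new parameter bundle; the input is never mutated. Only the
    female means of the selected dimensions move; variability parameters
    and all male values are untouched.
    """
    out = with_nonpa_minutes(params, spec.nonpa_minutes) \
        if spec.nonpa_minutes is not None else params.copy()
    r = spec.fraction

    def lerp(f, m):
        return f + r * (m - f)

    a = out.activity
    for dim in spec.dimensions:
        if dim == "pa_days":
            for g in AGE_GROUPS:
                a.active_days["female"][g].mean = lerp(
                    a.active_days["female"][g].mean, a.active_days["male"][g].mean)
        elif dim == "pa_intensity":
            a.intensity_met["female"].mean = lerp(
                a.intensity_met["female"].mean, a.intensity_met["male"].mean)
        elif dim == "pa_minutes":
            a.active_day_minutes["female"] = lerp(
                a.active_day_minutes["female"], a.active_day_minutes["male"])
        elif dim == "sports_participation":
            out.sports.participation["female"] = lerp(
                out.sports.participation["female"], out.sports.participation["male"])
        elif dim == "sports_mvpa":
            out.sports.mvpa_min_per_week["female"] = lerp(
                out.sports.mvpa_min_per_week["female"],
                out.sports.mvpa_min_per_week["male"])
    return out


# ---------------------------------------------------------------------------
# paired execution


@dataclass
class PreparedBaseline:
    """One cohort with its frozen intake schedule and baseline trajectories."""

    params: ModelParams
    cohort: Cohort
    ref: GrowthReference
    intake_weeks: np.ndarray
    base_child: ChildhoodResult
    base_adult: AdultResult | None
    base_ledger: LedgerArrays | None
    sim_seed: int
    disease_seed: int


@dataclass
class PairedOutcome:
    """Per-agent paired baseline/scenario results for one replicate."""

    cohort: Cohort
    base_child: ChildhoodResult
    scen_child: ChildhoodResult
    base_adult: AdultResult | None
    scen_adult: AdultResult | None
    base_ledger: LedgerArrays | None
    scen_ledger: LedgerArrays | None
    scale: float
    seed: int


def _child_seeds(seed: int) -> tuple:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    s = rng.integers(2 ** 31, size=3)
    return int(s[0]), int(s[1]), int(s[2])


def prepare_baseline(params: ModelParams, scale: float, seed: int,
                     include_adult: bool = True,
                     growth_ref: GrowthReference | None = None) -> PreparedBaseline:
    """Build the cohort and run the baseline arm once (shared across scenarios)."""
    ref = growth_ref if growth_ref is not None \
        else load_growth_reference(params.growth_reference)
    cohort_seed, sim_seed, disease_seed = _child_seeds(seed)
    cohort = build_cohort(params, scale, cohort_seed, growth_ref=ref)
    df = cohort.df
    sex_code = cohort.sex_code
    profile = build_profile(df["sex"].to_numpy(), df["age_group"].to_numpy(),
                            df["sports_uniform"].to_numpy(), params.activity,
                            params.sports)
    e_act = expected_activity_per_kg(profile, params.metabolic)
    intake = maintenance_intake_path(df["ffm_kg"].to_numpy(), df["fm_kg"].to_numpy(),
                                     df["age"].to_numpy(), sex_code, e_act, ref,
                                     params.metabolic)
    base_child = simulate_childhood_cohort(df["ffm_kg"].to_numpy(),
                                           df["fm_kg"].to_numpy(),
                                           df["age"].to_numpy(), sex_code, profile,
                                           intake, params.metabolic, ref, sim_seed)
    base_adult = base_ledger = None
    if include_adult:
        tables = compile_disease(params.disease)
        base_adult = simulate_adult_cohort(sex_code, base_child.weight_category,
                                           params.disease, disease_seed, tables)
        base_ledger = accrue_cohort(base_adult, df["age"].to_numpy(), params.economics)
    return PreparedBaseline(params=params, cohort=cohort, ref=ref, intake_weeks=intake,
                            base_child=base_child, base_adult=base_adult,
                            base_ledger=base_ledger, sim_seed=sim_seed,
                            disease_seed=disease_seed)


def run_counterfactual(prep: PreparedBaseline, scenario_params: ModelParams,
                       seed: int) -> PairedOutcome:
    """Run the scenario arm against a prepared baseline with shared randomness.

    The cohort, the frozen maintenance-intake schedule and every random
    stream are reused, so a scenario equal to the baseline reproduces it
    bit for bit and paired deltas carry no cohort-sampling noise.
    """
    params = prep.params
    df = prep.cohort.df
    sex_code = prep.cohort.sex_code
    scen_profile = build_profile(df["sex"].to_numpy(), df["age_group"].to_numpy(),
                                 df["sports_uniform"].to_numpy(),
                                 scenario_params.activity, scenario_params.sports)
    scen_child = simulate_childhood_cohort(df["ffm_kg"].to_numpy(),
                                           df["fm_kg"].to_numpy(),
                                           df["age"].to_numpy(), sex_code,
                                           scen_profile, prep.intake_weeks,
                                           params.metabolic, prep.ref, prep.sim_seed)
    scen_adult = scen_ledger = None
    if prep.base_adult is not None:
        tables = compile_disease(params.disease)
        scen_adult = simulate_adult_cohort(sex_code, scen_child.weight_category,
                                           params.disease, prep.disease_seed, tables)
        scen_ledger = accrue_cohort(scen_adult, df["age"].to_numpy(), params.economics)
    return PairedOutcome(cohort=prep.cohort, base_child=prep.base_child,
                         scen_child=scen_child, base_adult=prep.base_adult,
                         scen_adult=scen_adult, base_ledger=prep.base_ledger,
                         scen_ledger=scen_ledger, scale=prep.cohort.scale, seed=seed)


def run_replicate(params: ModelParams, scenario_params: ModelParams, scale: float,
                  seed: int, include_adult: bool = True,
                  growth_ref: GrowthReference | None = None) -> PairedOutcome:
    """One paired baseline-vs-scenario replicate on a fresh cohort."""
    prep = prepare_baseline(params, scale, seed, include_adult, growth_ref)
    return run_counterfactual(prep, scenario_params, seed)


# ---------------------------------------------------------------------------
# outcome accounting


def replicate_deltas(paired: PairedOutcome) -> pd.DataFrame:
    """Tidy cohort-level paired deltas: columns (outcome, age_group, value).

    Counts and dollars are at cohort scale (national scaling happens in
    :func:`summarize`); ``prevalence_change_pp`` is in percentage points.
    """
    df = paired.cohort.df
    female = (df["sex"] == "female").to_numpy()
    groups = {g: (df["age_group"] == g).to_numpy() for g in AGE_GROUPS}
    groups["total"] = np.ones(len(df), bool)

    owob_base = paired.base_child.weight_category >= 1
    owob_scen = paired.scen_child.weight_category >= 1

    rows = []

    def add(outcome, values_by_group):
        for g, v in values_by_group.items():
            rows.append({"outcome": outcome, "age_group": g, "value": float(v)})

    add("overweight_obesity_cases_averted",
        {g: np.sum((owob_base.astype(int) - owob_scen.astype(int))[female & m])
         for g, m in groups.items()})
    add("prevalence_change_pp",
        {g: 100.0 * (np.mean(owob_base[m]) - np.mean(owob_scen[m]))
         for g, m in groups.items()})

    if paired.base_adult is not None:
        names = paired.base_adult.names
        onsets_base = paired.base_adult.onsets()
        onsets_scen = paired.scen_adult.onsets()
        for cond in REPORTED_CONDITIONS:
            i = names.index(cond)
            add(f"{cond}_cases_averted",
                {g: np.sum((onsets_base[:, i].astype(int)
                            - onsets_scen[:, i].astype(int))[female & m])
                 for g, m in groups.items()})
            add(f"{cond}_deaths_averted",
                {g: np.sum(((paired.base_adult.cause == i).astype(int)
                            - (paired.scen_adult.cause == i).astype(int))[female & m])
                 for g, m in groups.items()})
        add("weight_related_cases_averted",
            {g: sum(np.sum((onsets_base[:, names.index(c)].astype(int)
                            - onsets_scen[:, names.index(c)].astype(int))[female & m])
                    for c in REPORTED_CONDITIONS)
             for g, m in groups.items()})
        lb, ls = paired.base_ledger, paired.scen_ledger
        add("qalys_saved", {g: np.sum((ls.qalys - lb.qalys)[female & m])
                            for g, m in groups.items()})
        add("life_years_saved",
            {g: np.sum((ls.life_years - lb.life_years)[female & m])
             for g, m in groups.items()})
        add("direct_savings_usd",
            {g: np.sum((lb.direct_usd - ls.direct_usd)[female & m])
             for g, m in groups.items()})
        add("productivity_savings_usd",
            {g: np.sum((lb.productivity_usd - ls.productivity_usd)[female & m])
             for g, m in groups.items()})
        add("societal_savings_usd",
            {g: np.sum((lb.societal_usd - ls.societal_usd)[female & m])
             for g, m in groups.items()})
    return pd.DataFrame(rows)


@dataclass
class OutcomeSummary:
    """Replicate mean with a percentile-bootstrap 95% CI per outcome and age group."""

    table: pd.DataFrame          # outcome, age_group, mean, ci_lo, ci_hi
    n_replicates: int
    scale: float

    def value(self, outcome: str, age_group: str = "total") -> float:
        t = self.table
        row = t[(t["outcome"] == outcome) & (t["age_group"] == age_group)]
        return float(row["mean"].iloc[0])


def summarize(replicates: list, scale: float, n_boot: int = 2000) -> OutcomeSummary:
    """Scale replicate deltas to national counts and pool across replicates.

    Counts and dollars are divided by the cohort scale; rate outcomes are
    left as-is. The 95% CI is a percentile bootstrap of the replicate mean
    (2.5th-97.5th percentiles of ``n_boot`` resampled means, fixed internal
    seed so summaries are reproducible).
    """
    if len(replicates) < 2:
        raise ValueError(f"need >= 2 replicates, got {len(replicates)}")
    frames = []
    for i, rep in enumerate(replicates):
        d = (rep if isinstance(rep, pd.DataFrame) else replicate_deltas(rep)).copy()
        d["replicate"] = i
        scaled = ~d["outcome"].isin(RATE_OUTCOMES)
        d.loc[scaled, "value"] = d.loc[scaled, "value"] / scale
        frames.append(d)
    pooled = pd.concat(frames, ignore_index=True)
    rng = np.random.default_rng(12345)
    rows = []
    for (outcome, group), sub in pooled.groupby(["outcome", "age_group"], sort=False):
        v = sub["value"].to_numpy()
        boot_means = v[rng.integers(0, len(v), size=(n_boot, len(v)))].mean(axis=1)
        rows.append({"outcome": outcome, "age_group": group, "mean": v.mean(),
                     "ci_lo": float(np.percentile(boot_means, 2.5)),
                     "ci_hi": float(np.percentile(boot_means, 97.5))})
    return OutcomeSummary(table=pd.DataFrame(rows), n_replicates=len(replicates),
                          scale=scale)


def run_experiment_grid(params: ModelParams, dimensions, fractions=(0.25, 0.5, 0.75, 1.0),
                        scale: float = 0.001, n_replicates: int = 25,
                        base_seed: int = 0, nonpa_minutes: float | None = None,
                        include_adult: bool = True,
                        growth_ref: GrowthReference | None = None) -> dict:
    """Paired scenario grid over reduction fractions with shared baselines.

    Every replicate builds one cohort and runs the baseline arm once; each
    fraction's scenario arm reuses that cohort and its random streams.
    Returns ``{fraction: OutcomeSummary}``; :func:`grid_table` flattens the
    result for a fraction-vs-outcome CSV with CI bands.
    """
    fractions = tuple(fractions)
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    base = with_nonpa_minutes(params, nonpa_minutes) if nonpa_minutes is not None \
        else params
    scenario_params = {
        f: apply_disparity_reduction(base, ScenarioSpec(tuple(dimensions), f))
        for f in fractions}
    rep_seeds = [int(s) for s in
                 np.random.default_rng(np.random.SeedSequence(base_seed))
                 .integers(2 ** 31, size=n_replicates)]
    deltas = {f: [] for f in fractions}
    for seed in rep_seeds:
        prep = prepare_baseline(base, scale, seed, include_adult, growth_ref)
        for f in fractions:
            paired = run_counterfactual(prep, scenario_params[f], seed)
            deltas[f].append(replicate_deltas(paired))
    return {f: summarize(deltas[f], scale) for f in fractions}


def grid_table(summaries: dict) -> pd.DataFrame:
    """Flatten a fraction -> OutcomeSummary map into one tidy table."""
    frames = []
    for f, summary in summaries.items():
        t = summary.table.copy()
        t.insert(0, "fraction", f)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
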