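"""Adult lifetime disease progression in annual timesteps.

From age 18 each agent passes through an embedded Markov model of
weight-related conditions — stroke, coronary heart disease, type 2 diabetes
and its complications (neuropathy, retinopathy, nephropathy), and cancers —
plus death. Conditions are semi-independent hazards (they can co-occur):
each year every not-yet-active condition fires with probability
``baseline incidence(age, sex) x RR(weight category at 18)``, complications
only while diabetes is active; mortality then combines background risk and
per-active-condition excess hazards as independent draws
(``1 - prod(1 - q_i)``), with the cause attributed to the first hazard that
fires in a fixed order. Death absorbs; background mortality is forced to 1
at the configured maximum age.

Within-year evaluation order (onsets in the configured condition order,
diabetes before its complications, then mortality) is fixed for
reproducibility. Every agent-year consumes the same number of uniforms so
baseline and counterfactual runs can share random streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ADULT_AGE_BAND_BOUNDS, DiseaseModelParams

#: cause-of-death code for background (non-modelled) mortality
BACKGROUND = -1


class DiseaseParameterError(ValueError):
    pass


@dataclass
class HealthState:
    """Scalar adult health state for one agent."""

    age: int
    active: dict                 # condition name -> bool
    alive: bool = True


@dataclass
class DiseaseHistory:
    """Per-agent lifetime of condition onsets and death."""

    onset_age: dict              # condition name -> onset age (absent if never)
    death_age: int
    cause: str                   # condition name or 'background'


@dataclass
class CompiledDisease:
    """Transition tables expanded to per-year arrays for the vector kernel."""

    names: tuple
    incidence: np.ndarray        # (K, 2 sexes, max_age + 1) annual probability
    rr: np.ndarray               # (K, 3 weight categories)
    excess_mortality: np.ndarray  # (K,)
    requires: np.ndarray         # (K,) index of prerequisite condition or -1
    background: np.ndarray       # (max_age + 1,) annual probability
    max_age: int

    @property
    def n_conditions(self) -> int:
        return len(self.names)

    @property
    def draws_per_year(self) -> int:
        return 2 * self.n_conditions + 1


def compile_disease(params: DiseaseModelParams) -> CompiledDisease:
    """Expand banded tables to per-year arrays and check probability bounds."""
    names = params.condition_names
    k = len(names)
    max_age = params.max_age
    ages = np.arange(max_age + 1)

    incidence = np.zeros((k, 2, max_age + 1))
    rr = np.ones((k, 3))
    excess = np.zeros(k)
    requires = np.full(k, -1, dtype=int)
    for i, name in enumerate(names):
        c = params.conditions[name]
        for s_idx, sex in enumerate(("male", "female")):
            for band, q in c.incidence[sex].items():
                lo, hi = ADULT_AGE_BAND_BOUNDS[band]
                incidence[i, s_idx, (ages >= lo) & (ages < hi)] = q
        rr[i] = [c.rr["healthy"], c.rr["overweight"], c.rr["obesity"]]
        excess[i] = c.excess_mortality
        if c.requires is not None:
            requires[i] = names.index(c.requires)
            if requires[i] >= i:
                raise DiseaseParameterError(
                    f"{name} requires {c.requires}, which must come earlier in the "
                    "condition order")

    if np.any(incidence[:, :, :, None] * rr[:, None, None, :] > 1.0 + 1e-12):
        raise DiseaseParameterError("incidence x relative risk exceeds 1 for some stratum")

    background = np.minimum(params.gompertz_a * np.exp(params.gompertz_b * ages), 1.0)
    background[max_age:] = 1.0
    return CompiledDisease(names=names, incidence=incidence, rr=rr,
                           excess_mortality=excess, requires=requires,
                           background=background, max_age=max_age)


def annual_transition_kernel(age: int, active: np.ndarray, alive: np.ndarray,
                             sex_code: np.ndarray, category: np.ndarray,
                             tables: CompiledDisease, uniforms: np.ndarray):
    """One model year for the whole cohort, in place.

    ``active`` is (n, K) bool, ``uniforms`` is (n, 2K+1). Returns
    ``(new_onset, died, cause)`` where ``new_onset`` is (n, K) bool for this
    year's onsets, ``died`` is (n,) bool and ``cause`` holds condition
    indices (or BACKGROUND) for agents that died this year.
    """
    k = tables.n_conditions
    new_onset = np.zeros_like(active)
    for i in range(k):
        p = tables.incidence[i, sex_code, age] * tables.rr[i, category]
        eligible = alive & ~active[:, i]
        if tables.requires[i] >= 0:
            eligible &= active[:, tables.requires[i]]
        fired = eligible & (uniforms[:, i] < p)
        active[:, i] |= fired
        new_onset[:, i] = fired

    # mortality: background first, then per-condition excess hazards
    cause = np.full(len(alive), BACKGROUND, dtype=int)
    dead_bg = alive & (uniforms[:, 2 * k] < tables.background[age])
    died = dead_bg.copy()
    for i in range(k):
        fired = alive & active[:, i] & (uniforms[:, k + i] < tables.excess_mortality[i])
        newly = fired & ~died
        cause[newly] = i
        died |= fired
    cause[dead_bg] = BACKGROUND
    return new_onset, died, cause


@dataclass
class AdultResult:
    """Vectorised lifetime histories for a cohort entering adulthood at 18."""

    names: tuple
    onset_age: np.ndarray        # (n, K) float, NaN if never
    death_age: np.ndarray        # (n,) int
    cause: np.ndarray            # (n,) int, condition index or BACKGROUND

    def onsets(self) -> np.ndarray:
        """(n, K) bool: condition ever occurred."""
        return ~np.isnan(self.onset_age)


def simulate_adult_cohort(sex_code, category, params: DiseaseModelParams,
                          seed, tables: CompiledDisease | None = None) -> AdultResult:
    """Simulate every agent's adult life from age 18 to death.

    Identical seeds give identical uniform streams regardless of the weight
    categories passed in, so paired counterfactual runs are coupled: with
    all relative risks equal to 1 the category has no effect at all, and
    raising a relative risk can only add onsets agent by agent.
    """
    if tables is None:
        tables = compile_disease(params)
    sex_code = np.asarray(sex_code)
    category = np.asarray(category)
    n = len(sex_code)
    k = tables.n_conditions

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    active = np.zeros((n, k), bool)
    alive = np.ones(n, bool)
    onset_age = np.full((n, k), np.nan)
    death_age = np.full(n, tables.max_age, dtype=int)
    cause = np.full(n, BACKGROUND, dtype=int)

    for age in range(18, tables.max_age):
        u = rng.random((n, tables.draws_per_year))
        if not np.any(alive):
            continue
        new_onset, died, year_cause = annual_transition_kernel(
            age, active, alive, sex_code, category, tables, u)
        for i in range(k):
            onset_age[new_onset[:, i], i] = age
        newly_dead = alive & died
        death_age[newly_dead] = age + 1
        cause[newly_dead] = year_cause[newly_dead]
        alive &= ~died
    # background mortality is forced to 1 at max_age; anyone alive dies there
    return AdultResult(names=tables.names, onset_age=onset_age,
                       death_age=death_age, cause=cause)


def annual_transition(state: HealthState, weight_category: int, sex: str,
                      params: DiseaseModelParams, rng: np.random.Generator,
                      tables: CompiledDisease | None = None) -> HealthState:
    """Scalar one-year transition for a single agent (wraps the vector kernel)."""
    if not state.alive:
        raise ValueError("annual_transition requires a living agent")
    if tables is None:
        tables = compile_disease(params)
    active = np.array([[state.active.get(nm, False) for nm in tables.names]])
    alive = np.array([True])
    sex_code = np.array([0 if sex == "male" else 1])
    cat = np.array([int(weight_category)])
    u = rng.random((1, tables.draws_per_year))
    _, died, _ = annual_transition_kernel(state.age, active, alive, sex_code, cat,
                                          tables, u)
    return HealthState(age=state.age + 1,
                       active={nm: bool(active[0, i]) for i, nm in enumerate(tables.names)},
                       alive=not bool(died[0]))


def simulate_adult_life(weight_category: int, sex: str, params: DiseaseModelParams,
                        rng_or_seed) -> DiseaseHistory:
    """Scalar lifetime simulation for one agent starting at age 18."""
    seed = rng_or_seed if isinstance(rng_or_seed, (int, np.integer)) \
        else rng_or_seed.integers(2 ** 31)
    res = simulate_adult_cohort(np.array([0 if sex == "male" else 1]),
                                np.array([int(weight_category)]), params, seed)
    onsets = {nm: int(res.onset_age[0, i])
              for i, nm in enumerate(res.names) if not np.isnan(res.onset_age[0, i])}
    cause = "background" if res.cause[0] == BACKGROUND else res.names[res.cause[0]]
    return DiseaseHistory(onset_age=onsets, death_age=int(res.death_age[0]), cause=cause)
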