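"""Daily energy-balance weight dynamics until age 18.

The childhood model advances in one-day steps. Each day an agent's caloric
surplus ``S = intake - resting - activity`` is partitioned between the
fat-free and fat compartments with a Forbes-style fat-free share
``p = C / (C + fat mass)`` and converted to mass by the tissue energy
densities (defaults 9441 kcal/kg fat, 1807 kcal/kg lean), so energy is
conserved exactly: ``rho_F * dFM + rho_L * dFFM = S`` whenever no physiologic
mass floor is hit.

Caloric intake follows the maintenance rule: every agent eats the amount
that keeps its BMI-for-age *percentile* constant along the growth reference
given its baseline expected activity. That intake path is computed in closed
form (the daily surplus needed to track the percentile-constant mass
trajectory) and frozen: counterfactual scenarios raise activity without
touching intake, so extra expenditure becomes a caloric deficit and weight
loss relative to baseline — the model's causal pathway. A constant-intake
variant solved by bisection over an arbitrary horizon is also provided.

Resting expenditure is linear in fat-free and fat mass with sex-specific
coefficients, plus a flat growth-energy term for minors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import ndtr

from .activity import WEEKLY_DRAWS, ActivityProfile, draw_week, expected_daily_kcal_per_kg
from .growth import GrowthReference
from .params import MetabolicConstants

DAYS_PER_YEAR = 365
DT_YEARS = 1.0 / DAYS_PER_YEAR
ADULT_AGE = 18.0


class MaintenanceSolveError(RuntimeError):
    """Bisection on maintenance intake failed to bracket the target percentile."""


@dataclass
class MetabolicState:
    """Scalar energy-balance state for a single agent."""

    fat_mass: float
    fat_free_mass: float
    maintenance_intake: float = 0.0
    baseline_activity_kcal: float = 0.0

    @property
    def mass(self) -> float:
        return self.fat_mass + self.fat_free_mass


@dataclass
class ChildhoodResult:
    """End-of-childhood state plus bookkeeping ledgers (vector, one row per agent)."""

    ffm_kg: np.ndarray
    fm_kg: np.ndarray
    age: np.ndarray
    bmi: np.ndarray
    weight_category: np.ndarray      # adult cut points at age 18
    zscore: np.ndarray               # BMI-for-age z at the reference boundary
    net_energy_kcal: np.ndarray      # cumulative intake - expenditure
    mass_clipped: np.ndarray         # True where a physiologic floor engaged


def fat_free_share(fat_mass, constants: MetabolicConstants):
    """Forbes-style fat-free share of the energy partition, p = C / (C + FM)."""
    return constants.forbes_c_kg / (constants.forbes_c_kg + np.asarray(fat_mass, float))


def resting_kcal(sex_code, ffm, fm, age, constants: MetabolicConstants):
    """Resting + growth expenditure, kcal/day (vectorised)."""
    sex_code = np.asarray(sex_code)
    ffm = np.asarray(ffm, float)
    fm = np.asarray(fm, float)
    male, female = constants.resting["male"], constants.resting["female"]
    intercept = np.where(sex_code == 0, male.intercept_kcal, female.intercept_kcal)
    a = np.where(sex_code == 0, male.per_kg_ffm, female.per_kg_ffm)
    b = np.where(sex_code == 0, male.per_kg_fm, female.per_kg_fm)
    ree = intercept + a * ffm + b * fm
    return ree + np.where(np.asarray(age, float) < ADULT_AGE,
                          constants.growth_kcal_per_day_minor, 0.0)


def _resting_coeffs(sex_code, constants: MetabolicConstants, minor: bool = True):
    """Per-agent (intercept, per-kg-ffm, per-kg-fm) vectors for the day loops.

    The growth-energy term is folded into the intercept because every agent
    in the childhood loop is a minor.
    """
    sex_code = np.asarray(sex_code)
    male, female = constants.resting["male"], constants.resting["female"]
    ic = np.where(sex_code == 0, male.intercept_kcal, female.intercept_kcal)
    if minor:
        ic = ic + constants.growth_kcal_per_day_minor
    a = np.where(sex_code == 0, male.per_kg_ffm, female.per_kg_ffm)
    b = np.where(sex_code == 0, male.per_kg_fm, female.per_kg_fm)
    return ic, a, b


def _apply_surplus(ffm, fm, surplus, constants: MetabolicConstants):
    """Partition a daily surplus into mass changes; returns (ffm', fm', clipped)."""
    p = fat_free_share(fm, constants)
    d_ffm = p * surplus / constants.rho_lean_kcal_per_kg
    d_fm = (1.0 - p) * surplus / constants.rho_fat_kcal_per_kg
    ffm_new = ffm + d_ffm
    fm_new = fm + d_fm
    clipped = (fm_new < constants.fat_mass_floor_kg) | \
              (ffm_new < constants.fat_free_mass_floor_kg)
    return (np.maximum(ffm_new, constants.fat_free_mass_floor_kg),
            np.maximum(fm_new, constants.fat_mass_floor_kg),
            clipped)


def step_day(state: MetabolicState, intake_kcal: float, activity_kcal: float,
             resting_kcal_day: float, constants: MetabolicConstants) -> MetabolicState:
    """One day of energy balance for a single agent.

    Surplus ``S = intake - resting - activity`` moves mass at fixed tissue
    energy densities; at zero surplus the state is unchanged, and a +S step
    followed by a -S step at the same partition returns the original masses.
    """
    if not all(map(math.isfinite, (intake_kcal, activity_kcal, resting_kcal_day))):
        raise ValueError("intake, activity and resting kcal must be finite")
    s = intake_kcal - resting_kcal_day - activity_kcal
    ffm, fm, _ = _apply_surplus(np.float64(state.fat_free_mass),
                                np.float64(state.fat_mass), np.float64(s), constants)
    return MetabolicState(fat_mass=float(fm), fat_free_mass=float(ffm),
                          maintenance_intake=state.maintenance_intake,
                          baseline_activity_kcal=state.baseline_activity_kcal)


@njit(cache=True)
def _path_week(ffm, fm, age, dm_day, e_act, ic, ca, cb, forbes_c, rho_f, rho_l,
               adult_age, dt, intake_out):  # pragma: no cover - numba kernel
    """Seven days of the deterministic percentile-constant intake path."""
    n = ffm.shape[0]
    for i in range(n):
        f, m, a = ffm[i], fm[i], age[i]
        total = 0.0
        for _ in range(7):
            if a >= adult_age:
                break
            p = forbes_c / (forbes_c + m)
            kappa = p / rho_l + (1.0 - p) / rho_f
            s = dm_day[i] / kappa
            total += ic[i] + ca[i] * f + cb[i] * m + e_act[i] * (f + m) + s
            f += p * s / rho_l
            m += (1.0 - p) * s / rho_f
            a += dt
        ffm[i], fm[i], age[i] = f, m, a
        intake_out[i] = total / 7.0


@njit(cache=True)
def _sim_week(ffm, fm, age, active_days, coef_active, coef_rest, coef_sport,
              intake, ic, ca, cb, forbes_c, rho_f, rho_l, fm_floor, ffm_floor,
              adult_age, dt, net, clipped):  # pragma: no cover - numba kernel
    """Seven days of stochastic energy balance for every active agent."""
    n = ffm.shape[0]
    for i in range(n):
        f, m, a = ffm[i], fm[i], age[i]
        if a >= adult_age:
            continue
        for d in range(7):
            if a >= adult_age:
                break
            act = coef_rest[i]
            if d < active_days[i]:
                act = coef_active[i]
            s = intake[i] - (ic[i] + ca[i] * f + cb[i] * m) \
                - (act + coef_sport[i]) * (f + m)
            p = forbes_c / (forbes_c + m)
            f_new = f + p * s / rho_l
            m_new = m + (1.0 - p) * s / rho_f
            if m_new < fm_floor or f_new < ffm_floor:
                clipped[i] = True
                if m_new < fm_floor:
                    m_new = fm_floor
                if f_new < ffm_floor:
                    f_new = ffm_floor
            f, m = f_new, m_new
            net[i] += s
            a += dt
        ffm[i], fm[i], age[i] = f, m, a


def _n_weeks(age0: np.ndarray) -> int:
    longest_days = float(np.max(ADULT_AGE - np.asarray(age0, float))) * DAYS_PER_YEAR
    return max(1, int(math.ceil(longest_days / 7.0)) + 1)


def maintenance_intake_path(ffm0, fm0, age0, sex_code, expected_activity_per_kg,
                            ref: GrowthReference, constants: MetabolicConstants):
    """Closed-form daily maintenance intake, averaged per week, frozen at baseline.

    Follows each agent's percentile-constant trajectory deterministically:
    each day the surplus needed to move total mass to the next day's
    reference mass (same z-score, grown height and age) is added to resting
    and expected-activity expenditure. Returns an ``(n, n_weeks)`` array of
    kcal/day, constant within each week.
    """
    ffm = np.array(ffm0, float, copy=True)
    fm = np.array(fm0, float, copy=True)
    age = np.array(age0, float, copy=True)
    sex_code = np.asarray(sex_code)
    e_act = np.ascontiguousarray(
        np.broadcast_to(np.asarray(expected_activity_per_kg, float), ffm.shape))

    h0 = ref.median_height(age, sex_code)
    z0 = ref.zscore(age, sex_code, (ffm + fm) / h0 ** 2)

    n = len(ffm)
    n_weeks = _n_weeks(age)
    intake = np.zeros((n, n_weeks))

    rho_f, rho_l = constants.rho_fat_kcal_per_kg, constants.rho_lean_kcal_per_kg
    ic, ca, cb = _resting_coeffs(sex_code, constants)
    for week in range(n_weeks):
        if not np.any(age < ADULT_AGE):
            break
        # the reference trajectory is smooth: anchor the mass target at the
        # week's end and spread the increment evenly over its seven days
        age_end = age + 7 * DT_YEARS
        a_clip = np.minimum(age_end, ref.age_max)
        h_end = ref.median_height(age_end, sex_code)
        dm_day = (ref.bmi_from_zscore(a_clip, sex_code, z0) * h_end * h_end
                  - (ffm + fm)) / 7.0
        _path_week(ffm, fm, age, dm_day, e_act, ic, ca, cb, constants.forbes_c_kg,
                   rho_f, rho_l, ADULT_AGE, DT_YEARS, intake[:, week])
    return intake


def simulate_childhood_cohort(ffm0, fm0, age0, sex_code, profile: ActivityProfile,
                              intake_weeks: np.ndarray, constants: MetabolicConstants,
                              ref: GrowthReference, seed) -> ChildhoodResult:
    """Stochastic daily simulation of the whole cohort until age 18.

    Weekly activity schedules are drawn through a fixed number of inverse-CDF
    uniforms per agent-week from a generator seeded with ``seed``; running
    baseline and counterfactual parameters with the same seed therefore
    couples them through common random numbers. ``intake_weeks`` is the
    frozen maintenance-intake schedule from :func:`maintenance_intake_path`.
    """
    ffm = np.array(ffm0, float, copy=True)
    fm = np.array(fm0, float, copy=True)
    age = np.array(age0, float, copy=True)
    sex_code = np.asarray(sex_code)
    n = len(ffm)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    c = constants.kcal_per_kg_met_min
    net = np.zeros(n)
    clipped_any = np.zeros(n, bool)

    ic, ca, cb = _resting_coeffs(sex_code, constants)
    n_weeks = intake_weeks.shape[1]
    for week in range(n_weeks):
        # always consume the same number of uniforms (common-random-number contract)
        u = rng.random((n, WEEKLY_DRAWS))
        if not np.any(age < ADULT_AGE):
            continue
        days, met, sports_met = draw_week(profile, u)
        coef_active = (met - 1.0) * c * profile.active_minutes
        coef_rest = (met - 1.0) * c * profile.nonactive_minutes
        coef_sport = np.where(profile.sports_participant,
                              (sports_met - 1.0) * c * profile.sports_mvpa / 7.0, 0.0)
        _sim_week(ffm, fm, age, days, coef_active, coef_rest, coef_sport,
                  intake_weeks[:, week], ic, ca, cb, constants.forbes_c_kg,
                  constants.rho_fat_kcal_per_kg, constants.rho_lean_kcal_per_kg,
                  constants.fat_mass_floor_kg, constants.fat_free_mass_floor_kg,
                  ADULT_AGE, DT_YEARS, net, clipped_any)

    mass = ffm + fm
    height = ref.median_height(age, sex_code)
    bmi = mass / height ** 2
    z = ref.zscore(np.minimum(age, ref.age_max), sex_code, bmi)
    category = ref.classify(age, sex_code, bmi)
    return ChildhoodResult(ffm_kg=ffm, fm_kg=fm, age=age, bmi=bmi,
                           weight_category=category, zscore=z,
                           net_energy_kcal=net, mass_clipped=clipped_any)


def maintenance_intake(ffm, fm, age, sex_code, expected_activity_per_kg,
                       ref: GrowthReference, constants: MetabolicConstants,
                       horizon_days: int = 365, tol_kcal: float = 1.0,
                       percentile_tol: float = 0.005):
    """Constant daily intake holding BMI percentile over a horizon (bisection).

    Deterministic forward simulation at expected activity; the returned
    intake changes the BMI-for-age percentile by less than
    ``percentile_tol`` over ``horizon_days`` (height growth included, so
    absolute BMI may drift while the percentile does not). Vectorised over
    agents; scalars are accepted and returned as floats.
    """
    scalar_in = np.isscalar(ffm) or np.ndim(ffm) == 0
    ffm0 = np.atleast_1d(np.asarray(ffm, float))
    fm0 = np.atleast_1d(np.asarray(fm, float))
    age0 = np.atleast_1d(np.asarray(age, float))
    sex0 = np.atleast_1d(np.asarray(sex_code))
    e_act = np.broadcast_to(np.asarray(expected_activity_per_kg, float), ffm0.shape)

    h = ref.median_height(age0, sex0)
    p_start = ndtr(ref.zscore(age0, sex0, (ffm0 + fm0) / h ** 2))

    def final_percentile(intake):
        ffm_, fm_, age_ = ffm0.copy(), fm0.copy(), age0.copy()
        for _ in range(horizon_days):
            m = ffm_ + fm_
            surplus = intake - resting_kcal(sex0, ffm_, fm_, age_, constants) - e_act * m
            ffm_, fm_, _ = _apply_surplus(ffm_, fm_, surplus, constants)
            age_ = age_ + DT_YEARS
        a_end = np.minimum(age_, ref.age_max)
        h_end = ref.median_height(age_, sex0)
        return ndtr(ref.zscore(a_end, sex0, (ffm_ + fm_) / h_end ** 2))

    lo = np.zeros_like(ffm0)
    hi = 4.0 * resting_kcal(sex0, ffm0, fm0, age0, constants) + \
        3.0 * e_act * (ffm0 + fm0) + 3000.0
    f_lo = final_percentile(lo) - p_start
    f_hi = final_percentile(hi) - p_start
    if np.any(f_lo > 0) or np.any(f_hi < 0):
        bad = np.where((f_lo > 0) | (f_hi < 0))[0]
        raise MaintenanceSolveError(
            f"intake bracket failure for agents {bad[:10].tolist()}: "
            f"f(lo)={f_lo[bad[:10]].tolist()}, f(hi)={f_hi[bad[:10]].tolist()}")

    n_iter = int(math.ceil(math.log2(float(np.max(hi - lo)) / tol_kcal)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        too_high = (final_percentile(mid) - p_start) > 0
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    intake = 0.5 * (lo + hi)

    drift = np.abs(final_percentile(intake) - p_start)
    if np.any(drift > percentile_tol):
        bad = np.where(drift > percentile_tol)[0]
        raise MaintenanceSolveError(
            f"maintenance intake leaves percentile drift {drift[bad[:10]].tolist()} "
            f"> {percentile_tol} for agents {bad[:10].tolist()}")
    return float(intake[0]) if scalar_in else intake


def expected_activity_per_kg(profile: ActivityProfile,
                             constants: MetabolicConstants) -> np.ndarray:
    """Expected daily net activity kcal per kg under a given activity profile."""
    return expected_daily_kcal_per_kg(profile, constants.kcal_per_kg_met_min)
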