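"""Lifetime cost and QALY accrual under two costing perspectives.

Agents accrue, year by year from simulation entry to death:

* QALYs — one year weighted by the product of active-condition utility
  weights (healthy utility 1.0; multiplicative under comorbidity so the
  combined weight stays in [0, 1]), discounted to entry;
* direct medical costs — the sum of active-condition annual costs
  (third-party payer perspective);
* productivity losses from presenteeism — daily wage x (1 - combined
  utility weight) x days, accrued by every agent regardless of age or
  employment, discounted likewise (societal = direct + productivity,
  exactly, for every agent).

Conditions persist from onset to death. Childhood years (entry to 18)
accrue QALYs at the healthy utility and no disease costs, since disease
onset begins with the adult model. All values are net present value at a
fixed annual rate (default 3%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disease import AdultResult, DiseaseHistory
from .params import EconParams

DAYS_PER_YEAR = 365.0
ADULT_AGE = 18.0


@dataclass
class CostLedger:
    """Discounted lifetime totals for one agent."""

    qalys: float
    direct_usd: float
    productivity_usd: float
    life_years: float            # undiscounted
    disc_life_years: float

    @property
    def societal_usd(self) -> float:
        return self.direct_usd + self.productivity_usd


@dataclass
class LedgerArrays:
    """Vectorised ledgers, one entry per agent; additive across agents."""

    qalys: np.ndarray
    direct_usd: np.ndarray
    productivity_usd: np.ndarray
    life_years: np.ndarray
    disc_life_years: np.ndarray

    @property
    def societal_usd(self) -> np.ndarray:
        return self.direct_usd + self.productivity_usd


def productivity_loss(daily_wage: float, utility_weight: float,
                      duration_days: float) -> float:
    """Presenteeism loss: daily wage x (1 - utility weight) x duration.

    A utility weight of 0.6 means the agent is 40% less productive.
    Undiscounted; discounting happens at accrual.
    """
    if daily_wage < 0 or duration_days < 0:
        raise ValueError("wage and duration must be non-negative")
    if not 0.0 <= utility_weight <= 1.0:
        raise ValueError(f"utility weight must be in [0, 1], got {utility_weight}")
    return daily_wage * (1.0 - utility_weight) * duration_days


def discount_to_present(amount, years_from_reference, rate):
    """Net present value: amount / (1 + rate) ** years."""
    if np.any(np.asarray(rate) < 0):
        raise ValueError("discount rate must be >= 0")
    return np.asarray(amount, float) / (1.0 + rate) ** np.asarray(years_from_reference, float)


def accrue_cohort(adult: AdultResult, entry_age, econ: EconParams) -> LedgerArrays:
    """Accrue discounted QALYs, direct costs and productivity losses per agent.

    ``entry_age`` is each agent's age at simulation start — the discounting
    reference point. Childhood (entry to 18) is healthy by construction;
    fractional childhood years are pro-rated.
    """
    for name in adult.names:
        if name not in econ.conditions:
            raise KeyError(f"no cost/utility entry for condition {name!r}")
    entry = np.asarray(entry_age, float)
    n = len(entry)
    r = econ.discount_rate
    wage_year = econ.daily_wage_usd * DAYS_PER_YEAR

    utilities = np.array([econ.conditions[nm].utility for nm in adult.names])
    costs = np.array([econ.conditions[nm].annual_cost_usd for nm in adult.names])

    qaly = np.zeros(n)
    direct = np.zeros(n)
    productivity = np.zeros(n)
    disc_ly = np.zeros(n)

    # childhood: entry .. 18, healthy utility, fractional last year pro-rated
    max_child_years = int(np.ceil(np.max(ADULT_AGE - entry))) if n else 0
    for t in range(max(max_child_years, 0)):
        w = np.clip(ADULT_AGE - entry - t, 0.0, 1.0)
        disc = (1.0 + r) ** (-float(t))
        qaly += w * econ.healthy_utility * disc
        disc_ly += w * disc
        productivity += w * wage_year * (1.0 - econ.healthy_utility) * disc

    # adulthood: 18 .. death, discount exponent measured from entry
    max_age = int(np.max(adult.death_age)) if n else 18
    for age in range(18, max_age):
        lived = age < adult.death_age
        if not np.any(lived):
            break
        active = adult.onset_age <= age          # (n, K); NaN compares False
        util = econ.healthy_utility * np.prod(np.where(active, utilities, 1.0), axis=1)
        cost = np.sum(np.where(active, costs, 0.0), axis=1)
        disc = (1.0 + r) ** (-(age - entry))
        qaly += np.where(lived, util * disc, 0.0)
        direct += np.where(lived, cost * disc, 0.0)
        productivity += np.where(lived, wage_year * (1.0 - util) * disc, 0.0)
        disc_ly += np.where(lived, disc, 0.0)

    life_years = (ADULT_AGE - entry) + (adult.death_age - ADULT_AGE)
    return LedgerArrays(qalys=qaly, direct_usd=direct, productivity_usd=productivity,
                        life_years=life_years, disc_life_years=disc_ly)


def accrue_lifetime(history: DiseaseHistory, econ: EconParams,
                    entry_age: float = 18.0) -> CostLedger:
    """Scalar lifetime accrual for a single agent's history."""
    names = tuple(econ.conditions)
    onset = np.full((1, len(names)), np.nan)
    for i, nm in enumerate(names):
        if nm in history.onset_age:
            onset[0, i] = history.onset_age[nm]
    adult = AdultResult(names=names, onset_age=onset,
                        death_age=np.array([history.death_age]),
                        cause=np.array([-1]))
    a = accrue_cohort(adult, np.array([entry_age]), econ)
    return CostLedger(qalys=float(a.qalys[0]), direct_usd=float(a.direct_usd[0]),
                      productivity_usd=float(a.productivity_usd[0]),
                      life_years=float(a.life_years[0]),
                      disc_life_years=float(a.disc_life_years[0]))
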