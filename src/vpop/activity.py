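"""Weekly physical-activity behaviour and its caloric cost.

Each simulated week an agent draws (i) a mean number of days with at least
60 minutes of physical activity from its age- and sex-specific distribution,
stochastically rounded to an integer count so the long-run mean equals the
drawn value, and (ii) a PA intensity in METs. On the remaining days the
agent gets a configurable number of non-PA-day minutes at the same
intensity. Sports participants additionally log a sex-specific weekly block
of moderate-vigorous minutes at a sports intensity drawn from a triangular
distribution honouring the published mean and range; the block is spread
evenly across the seven days and is strictly additive to non-sport PA.

Activity kcal are net of rest: each block contributes
``(MET - 1) * c * mass_kg * minutes`` with ``c`` the kcal-per-MET-minute
constant (default 3.5/200 kcal per kg per minute), so resting expenditure is
never double-counted against the metabolism module's maintenance term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dists import triangular_mean, triangular_ppf, truncnorm_mean, truncnorm_ppf
from .params import ActivityParams, SportsParams

DAYS_PER_WEEK = 7
DEFAULT_KCAL_PER_KG_MET_MIN = 3.5 / 200.0

#: uniforms consumed per agent per simulated week, in fixed order
WEEKLY_DRAWS = 4  # active-days level, stochastic rounding, PA MET, sports MET


@dataclass
class WeeklySchedule:
    """One agent-week of activity behaviour."""

    active_days: int                 # days with >= active_day_minutes of PA
    active_day_minutes: float
    nonactive_day_minutes: float
    intensity_met: float             # non-sport PA intensity
    sports_mvpa_min: float           # weekly sports minutes (0 for non-participants)
    sports_met: float


@dataclass
class ActivityProfile:
    """Per-agent activity parameter vectors (scenario-aware)."""

    mu_days: np.ndarray
    sd_days: np.ndarray
    active_minutes: np.ndarray
    nonactive_minutes: np.ndarray
    met_mean: np.ndarray
    met_sd: np.ndarray
    sports_participant: np.ndarray   # bool
    sports_mvpa: np.ndarray
    sports_met_lo: np.ndarray
    sports_met_mode: np.ndarray
    sports_met_hi: np.ndarray

    def __len__(self) -> int:
        return len(self.mu_days)


def build_profile(sex, age_group, sports_uniform, activity: ActivityParams,
                  sports: SportsParams) -> ActivityProfile:
    """Expand stratum-level parameters into per-agent vectors.

    ``sports_uniform`` is the stored uniform behind each agent's
    participation Bernoulli; evaluating it against the current sex-specific
    probability makes participation respond to counterfactual participation
    levels while staying coupled across scenarios.
    """
    sex = np.asarray(sex)
    age_group = np.asarray(age_group)
    n = len(sex)

    def per_agent(getter):
        out = np.empty(n, float)
        for s in ("male", "female"):
            for g in ("6-11", "12-17"):
                m = (sex == s) & (age_group == g)
                if np.any(m):
                    out[m] = getter(s, g)
        return out

    def per_sex(getter):
        out = np.empty(n, float)
        for s in ("male", "female"):
            m = sex == s
            if np.any(m):
                out[m] = getter(s)
        return out

    part_prob = per_sex(lambda s: sports.participation[s])
    return ActivityProfile(
        mu_days=per_agent(lambda s, g: activity.active_days[s][g].mean),
        sd_days=per_agent(lambda s, g: activity.active_days[s][g].sd),
        active_minutes=per_sex(lambda s: activity.active_day_minutes[s]),
        nonactive_minutes=per_sex(lambda s: activity.nonactive_day_minutes[s]),
        met_mean=per_sex(lambda s: activity.intensity_met[s].mean),
        met_sd=per_sex(lambda s: activity.intensity_met[s].sd),
        sports_participant=np.asarray(sports_uniform, float) < part_prob,
        sports_mvpa=per_sex(lambda s: sports.mvpa_min_per_week[s]),
        sports_met_lo=per_sex(lambda s: sports.intensity_met[s].min),
        sports_met_mode=per_sex(lambda s: sports.intensity_met[s].mean),
        sports_met_hi=per_sex(lambda s: sports.intensity_met[s].max),
    )


def draw_week(profile: ActivityProfile, uniforms: np.ndarray):
    """Vectorised weekly draw from a ``(n, WEEKLY_DRAWS)`` uniform block.

    Returns ``(active_days int, met, sports_met)``. The drawn mean days are
    truncated to [0, 7] and stochastically rounded (floor + Bernoulli on the
    fractional part); intensity is normal truncated at 1 MET; sports
    intensity is triangular over the published (min, mean, max).
    """
    d = truncnorm_ppf(uniforms[:, 0], profile.mu_days, profile.sd_days, 0.0, 7.0)
    base = np.floor(d)
    days = (base + (uniforms[:, 1] < (d - base))).astype(np.int8)
    met = truncnorm_ppf(uniforms[:, 2], profile.met_mean, profile.met_sd, lo=1.0)
    sports_met = triangular_ppf(uniforms[:, 3], profile.sports_met_lo,
                                profile.sports_met_mode, profile.sports_met_hi)
    return days, met, sports_met


def draw_weekly_schedule(sex: str, age_group: str, sports_participant: bool,
                         activity: ActivityParams, sports: SportsParams,
                         rng: np.random.Generator) -> WeeklySchedule:
    """Scalar weekly draw for a single agent."""
    profile = build_profile(np.array([sex]), np.array([age_group]),
                            np.array([0.0 if sports_participant else 1.0]),
                            activity, sports)
    days, met, s_met = draw_week(profile, rng.random((1, WEEKLY_DRAWS)))
    return WeeklySchedule(
        active_days=int(days[0]),
        active_day_minutes=float(profile.active_minutes[0]),
        nonactive_day_minutes=float(profile.nonactive_minutes[0]),
        intensity_met=float(met[0]),
        sports_mvpa_min=float(profile.sports_mvpa[0]) if sports_participant else 0.0,
        sports_met=float(s_met[0]),
    )


def daily_activity_kcal(schedule: WeeklySchedule, day_index: int, mass_kg: float,
                        kcal_per_kg_met_min: float = DEFAULT_KCAL_PER_KG_MET_MIN) -> float:
    """Net-of-rest activity kcal for one day of a weekly schedule.

    Days ``0 .. active_days-1`` are the active days; the rest are non-PA
    days. The weekly sports block contributes one seventh per day.
    """
    if not 0 <= day_index < DAYS_PER_WEEK:
        raise ValueError(f"day_index must be in 0..6, got {day_index}")
    minutes = (schedule.active_day_minutes if day_index < schedule.active_days
               else schedule.nonactive_day_minutes)
    if minutes < 0 or schedule.sports_mvpa_min < 0:
        raise ValueError("minutes must be non-negative")
    c = kcal_per_kg_met_min
    kcal = (schedule.intensity_met - 1.0) * c * mass_kg * minutes
    kcal += (schedule.sports_met - 1.0) * c * mass_kg * schedule.sports_mvpa_min / DAYS_PER_WEEK
    return float(kcal)


def expected_daily_kcal_per_kg(profile: ActivityProfile,
                               kcal_per_kg_met_min: float) -> np.ndarray:
    """Expected net activity kcal per kg of body mass per day.

    Uses the analytic truncated-normal means for active days and intensity
    (matching the stochastic draws exactly in expectation, including
    truncation and stochastic rounding) and the triangular mean for sports
    intensity. This is the 'baseline expected activity' the maintenance-
    intake rule conditions on.
    """
    e_days = truncnorm_mean(profile.mu_days, profile.sd_days, 0.0, 7.0)
    e_met = truncnorm_mean(profile.met_mean, profile.met_sd, lo=1.0)
    e_smet = triangular_mean(profile.sports_met_lo, profile.sports_met_mode,
                             profile.sports_met_hi)
    c = kcal_per_kg_met_min
    weekly = (e_days * profile.active_minutes
              + (DAYS_PER_WEEK - e_days) * profile.nonactive_minutes) * (e_met - 1.0) * c
    weekly = weekly + np.where(profile.sports_participant,
                               profile.sports_mvpa * (e_smet - 1.0) * c, 0.0)
    return weekly / DAYS_PER_WEEK
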