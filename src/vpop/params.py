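"""Parameter bundle: load, validate, default and round-trip every model input.

The packaged defaults (``data/defaults.yaml``) carry the published national
input values for demography, physical activity, sports participation, body
composition and overweight/obesity prevalence targets, together with
energy-balance constants and clearly-labelled placeholder disease and
cost/utility tables. A user config file supplies partial overrides that are
deep-merged onto the defaults, so a file overriding a single scalar leaves
everything else at its packaged value.

Validation is data, not exceptions: :func:`validate_params` returns a list of
:class:`Violation` records naming the offending field, its value and the rule
it breaks. :func:`load_params` raises :class:`ParamsError` only for structural
problems (unreadable file, unknown key, wrong type).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Any, Iterator, Mapping

import yaml

SEXES = ("male", "female")
AGE_GROUPS = ("6-11", "12-17")
#: Half-open age interval (years) covered by each age group.
AGE_GROUP_BOUNDS = {"6-11": (6.0, 12.0), "12-17": (12.0, 18.0)}
#: Fixed stratum order used everywhere counts are apportioned or reported.
STRATA = tuple((s, g) for g in AGE_GROUPS for s in SEXES)

WEIGHT_CATEGORIES = ("healthy", "overweight", "obesity")
ADULT_AGE_BANDS = ("18-39", "40-59", "60-79", "80+")
ADULT_AGE_BAND_BOUNDS = {
    "18-39": (18, 40), "40-59": (40, 60), "60-79": (60, 80), "80+": (80, 200),
}


class ParamsError(Exception):
    """Structural problem with a parameter file (missing, malformed, unknown key)."""


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which field, what value, which rule it breaks."""

    field: str
    value: Any
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field} = {self.value!r} violates: {self.rule}"


@dataclass
class MeanSD:
    mean: float
    sd: float


@dataclass
class MeanCI:
    mean: float
    lo: float
    hi: float


@dataclass
class TriangularMET:
    """Sports MET intensity summarised as mean with a (min, max) range."""

    mean: float
    min: float
    max: float


@dataclass
class DemographyParams:
    counts: dict          # sex -> age_group -> persons
    source: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts[s][g] for s, g in STRATA)


@dataclass
class ActivityParams:
    active_days: dict         # sex -> age_group -> MeanSD (days/week)
    intensity_met: dict       # sex -> MeanSD (METs)
    active_day_minutes: dict  # sex -> minutes of PA on an active day
    nonactive_day_minutes: dict  # sex -> minutes of PA on a non-PA day
    source: str = ""


@dataclass
class SportsParams:
    participation: dict       # sex -> probability
    mvpa_min_per_week: dict   # sex -> minutes/week
    intensity_met: dict       # sex -> TriangularMET
    source: str = ""


@dataclass
class BodyCompositionParams:
    fat_free_mass_kg: dict    # sex -> age_group -> MeanSD
    fat_mass: dict            # sex -> age_group -> MeanSD
    fat_mass_interpretation: str = "kg"   # 'kg' or 'ratio'
    age_scaling: bool = True
    source: str = ""


@dataclass
class PrevalenceTargets:
    overweight_pct: dict      # sex -> age_group -> MeanCI (percent)
    obesity_pct: dict
    source: str = ""


@dataclass
class RestingCoeffs:
    intercept_kcal: float
    per_kg_ffm: float
    per_kg_fm: float


@dataclass
class MetabolicConstants:
    rho_fat_kcal_per_kg: float
    rho_lean_kcal_per_kg: float
    forbes_c_kg: float
    kcal_per_kg_met_min: float
    resting: dict             # sex -> RestingCoeffs
    growth_kcal_per_day_minor: float
    fat_mass_floor_kg: float
    fat_free_mass_floor_kg: float
    source: str = ""


@dataclass
class ConditionParams:
    incidence: dict           # sex -> age_band -> annual probability
    rr: dict                  # weight category -> relative risk
    excess_mortality: float   # annual probability while the condition is active
    requires: str | None = None   # e.g. diabetes complications require diabetes


@dataclass
class DiseaseModelParams:
    max_age: int
    gompertz_a: float
    gompertz_b: float
    conditions: dict          # name -> ConditionParams, insertion-ordered
    source: str = ""
    background_source: str = ""

    @property
    def condition_names(self) -> tuple:
        return tuple(self.conditions)


@dataclass
class EconCondition:
    annual_cost_usd: float
    utility: float


@dataclass
class EconParams:
    discount_rate: float
    daily_wage_usd: float
    healthy_utility: float
    perspective: str          # 'societal' or 'third_party'
    conditions: dict          # name -> EconCondition
    source: str = ""


@dataclass
class ModelParams:
    """The full parameter bundle the simulation consumes."""

    demography: DemographyParams
    activity: ActivityParams
    sports: SportsParams
    body_composition: BodyCompositionParams
    prevalence_targets: PrevalenceTargets
    metabolic: MetabolicConstants
    disease: DiseaseModelParams
    economics: EconParams
    growth_reference: str | None = None

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return _params_to_dict(self)


# ---------------------------------------------------------------------------
# dict <-> dataclass plumbing


def _mean_sd(d: Mapping, where: str) -> MeanSD:
    try:
        return MeanSD(mean=float(d["mean"]), sd=float(d["sd"]))
    except (KeyError, TypeError) as exc:
        raise ParamsError(f"{where}: expected {{mean, sd}}, got {d!r}") from exc


def _mean_ci(d: Mapping, where: str) -> MeanCI:
    try:
        return MeanCI(mean=float(d["mean"]), lo=float(d["ci"][0]), hi=float(d["ci"][1]))
    except (KeyError, TypeError, IndexError) as exc:
        raise ParamsError(f"{where}: expected {{mean, ci: [lo, hi]}}, got {d!r}") from exc


def _by_sex_group(d: Mapping, leaf, where: str) -> dict:
    out: dict = {}
    for s in SEXES:
        if s not in d:
            raise ParamsError(f"{where}: missing sex {s!r}")
        out[s] = {}
        for g in AGE_GROUPS:
            if g not in d[s]:
                raise ParamsError(f"{where}.{s}: missing age group {g!r}")
            out[s][g] = leaf(d[s][g], f"{where}.{s}.{g}")
    return out


def _by_sex(d: Mapping, leaf, where: str) -> dict:
    out = {}
    for s in SEXES:
        if s not in d:
            raise ParamsError(f"{where}: missing sex {s!r}")
        out[s] = leaf(d[s], f"{where}.{s}")
    return out


def params_from_dict(cfg: Mapping) -> ModelParams:
    """Build a :class:`ModelParams` from a plain nested mapping."""

    def scalar(x, where):
        try:
            return float(x)
        except (TypeError, ValueError) as exc:
            raise ParamsError(f"{where}: expected a number, got {x!r}") from exc

    d = cfg.get("demography", {})
    demography = DemographyParams(
        counts=_by_sex_group(d.get("counts", {}), lambda x, w: int(x), "demography.counts"),
        source=str(d.get("source", "")),
    )

    a = cfg.get("activity", {})
    activity = ActivityParams(
        active_days=_by_sex_group(a.get("active_days", {}), _mean_sd, "activity.active_days"),
        intensity_met=_by_sex(a.get("intensity_met", {}), _mean_sd, "activity.intensity_met"),
        active_day_minutes=_by_sex(a.get("active_day_minutes", {}), scalar,
                                   "activity.active_day_minutes"),
        nonactive_day_minutes=_by_sex(a.get("nonactive_day_minutes", {}), scalar,
                                      "activity.nonactive_day_minutes"),
        source=str(a.get("source", "")),
    )

    s = cfg.get("sports", {})

    def tri(d_, where):
        try:
            return TriangularMET(mean=float(d_["mean"]), min=float(d_["min"]),
                                 max=float(d_["max"]))
        except (KeyError, TypeError) as exc:
            raise ParamsError(f"{where}: expected {{mean, min, max}}, got {d_!r}") from exc

    sports = SportsParams(
        participation=_by_sex(s.get("participation", {}), scalar, "sports.participation"),
        mvpa_min_per_week=_by_sex(s.get("mvpa_min_per_week", {}), scalar,
                                  "sports.mvpa_min_per_week"),
        intensity_met=_by_sex(s.get("intensity_met", {}), tri, "sports.intensity_met"),
        source=str(s.get("source", "")),
    )

    b = cfg.get("body_composition", {})
    body = BodyCompositionParams(
        fat_free_mass_kg=_by_sex_group(b.get("fat_free_mass_kg", {}), _mean_sd,
                                       "body_composition.fat_free_mass_kg"),
        fat_mass=_by_sex_group(b.get("fat_mass", {}), _mean_sd, "body_composition.fat_mass"),
        fat_mass_interpretation=str(b.get("fat_mass_interpretation", "kg")),
        age_scaling=bool(b.get("age_scaling", True)),
        source=str(b.get("source", "")),
    )

    p = cfg.get("prevalence_targets", {})
    prevalence = PrevalenceTargets(
        overweight_pct=_by_sex_group(p.get("overweight_pct", {}), _mean_ci,
                                     "prevalence_targets.overweight_pct"),
        obesity_pct=_by_sex_group(p.get("obesity_pct", {}), _mean_ci,
                                  "prevalence_targets.obesity_pct"),
        source=str(p.get("source", "")),
    )

    m = cfg.get("metabolic", {})

    def resting(d_, where):
        try:
            return RestingCoeffs(intercept_kcal=float(d_["intercept_kcal"]),
                                 per_kg_ffm=float(d_["per_kg_ffm"]),
                                 per_kg_fm=float(d_["per_kg_fm"]))
        except (KeyError, TypeError) as exc:
            raise ParamsError(f"{where}: bad resting coefficients {d_!r}") from exc

    metabolic = MetabolicConstants(
        rho_fat_kcal_per_kg=scalar(m.get("rho_fat_kcal_per_kg"), "metabolic.rho_fat_kcal_per_kg"),
        rho_lean_kcal_per_kg=scalar(m.get("rho_lean_kcal_per_kg"),
                                    "metabolic.rho_lean_kcal_per_kg"),
        forbes_c_kg=scalar(m.get("forbes_c_kg"), "metabolic.forbes_c_kg"),
        kcal_per_kg_met_min=scalar(m.get("kcal_per_kg_met_min"), "metabolic.kcal_per_kg_met_min"),
        resting=_by_sex(m.get("resting", {}), resting, "metabolic.resting"),
        growth_kcal_per_day_minor=scalar(m.get("growth_kcal_per_day_minor"),
                                         "metabolic.growth_kcal_per_day_minor"),
        fat_mass_floor_kg=scalar(m.get("fat_mass_floor_kg"), "metabolic.fat_mass_floor_kg"),
        fat_free_mass_floor_kg=scalar(m.get("fat_free_mass_floor_kg"),
                                      "metabolic.fat_free_mass_floor_kg"),
        source=str(m.get("source", "")),
    )

    dis = cfg.get("disease", {})
    conditions = {}
    for name, c in dis.get("conditions", {}).items():
        conditions[name] = ConditionParams(
            incidence=_by_sex(
                c.get("incidence", {}),
                lambda d_, w: {band: float(d_[band]) for band in ADULT_AGE_BANDS},
                f"disease.conditions.{name}.incidence"),
            rr={cat: float(c.get("rr", {}).get(cat, 1.0)) for cat in WEIGHT_CATEGORIES},
            excess_mortality=scalar(c.get("excess_mortality", 0.0),
                                    f"disease.conditions.{name}.excess_mortality"),
            requires=c.get("requires"),
        )
    bg = dis.get("background_mortality", {})
    disease = DiseaseModelParams(
        max_age=int(dis.get("max_age", 100)),
        gompertz_a=scalar(bg.get("gompertz_a"), "disease.background_mortality.gompertz_a"),
        gompertz_b=scalar(bg.get("gompertz_b"), "disease.background_mortality.gompertz_b"),
        conditions=conditions,
        source=str(dis.get("source", "")),
        background_source=str(bg.get("source", "")),
    )

    e = cfg.get("economics", {})
    econ_conditions = {
        name: EconCondition(annual_cost_usd=float(c["annual_cost_usd"]),
                            utility=float(c["utility"]))
        for name, c in e.get("conditions", {}).items()
    }
    economics = EconParams(
        discount_rate=scalar(e.get("discount_rate"), "economics.discount_rate"),
        daily_wage_usd=scalar(e.get("daily_wage_usd"), "economics.daily_wage_usd"),
        healthy_utility=scalar(e.get("healthy_utility", 1.0), "economics.healthy_utility"),
        perspective=str(e.get("perspective", "societal")),
        conditions=econ_conditions,
        source=str(e.get("source", "")),
    )

    return ModelParams(
        demography=demography,
        activity=activity,
        sports=sports,
        body_composition=body,
        prevalence_targets=prevalence,
        metabolic=metabolic,
        disease=disease,
        economics=economics,
        growth_reference=cfg.get("growth_reference"),
    )


def _params_to_dict(params: ModelParams) -> dict:
    def msd(x: MeanSD):
        return {"mean": x.mean, "sd": x.sd}

    def mci(x: MeanCI):
        return {"mean": x.mean, "ci": [x.lo, x.hi]}

    def nested(d, leaf):
        return {s: {g: leaf(v) for g, v in groups.items()} for s, groups in d.items()}

    out: dict = {
        "demography": {"source": params.demography.source,
                       "counts": copy.deepcopy(params.demography.counts)},
        "activity": {
            "source": params.activity.source,
            "active_days": nested(params.activity.active_days, msd),
            "intensity_met": {s: msd(v) for s, v in params.activity.intensity_met.items()},
            "active_day_minutes": dict(params.activity.active_day_minutes),
            "nonactive_day_minutes": dict(params.activity.nonactive_day_minutes),
        },
        "sports": {
            "source": params.sports.source,
            "participation": dict(params.sports.participation),
            "mvpa_min_per_week": dict(params.sports.mvpa_min_per_week),
            "intensity_met": {s: {"mean": v.mean, "min": v.min, "max": v.max}
                              for s, v in params.sports.intensity_met.items()},
        },
        "body_composition": {
            "source": params.body_composition.source,
            "fat_mass_interpretation": params.body_composition.fat_mass_interpretation,
            "age_scaling": params.body_composition.age_scaling,
            "fat_free_mass_kg": nested(params.body_composition.fat_free_mass_kg, msd),
            "fat_mass": nested(params.body_composition.fat_mass, msd),
        },
        "prevalence_targets": {
            "source": params.prevalence_targets.source,
            "overweight_pct": nested(params.prevalence_targets.overweight_pct, mci),
            "obesity_pct": nested(params.prevalence_targets.obesity_pct, mci),
        },
        "metabolic": {
            "source": params.metabolic.source,
            "rho_fat_kcal_per_kg": params.metabolic.rho_fat_kcal_per_kg,
            "rho_lean_kcal_per_kg": params.metabolic.rho_lean_kcal_per_kg,
            "forbes_c_kg": params.metabolic.forbes_c_kg,
            "kcal_per_kg_met_min": params.metabolic.kcal_per_kg_met_min,
            "resting": {s: asdict(v) for s, v in params.metabolic.resting.items()},
            "growth_kcal_per_day_minor": params.metabolic.growth_kcal_per_day_minor,
            "fat_mass_floor_kg": params.metabolic.fat_mass_floor_kg,
            "fat_free_mass_floor_kg": params.metabolic.fat_free_mass_floor_kg,
        },
        "growth_reference": params.growth_reference,
        "disease": {
            "source": params.disease.source,
            "max_age": params.disease.max_age,
            "background_mortality": {
                "source": params.disease.background_source,
                "gompertz_a": params.disease.gompertz_a,
                "gompertz_b": params.disease.gompertz_b,
            },
            "conditions": {
                name: {
                    **({"requires": c.requires} if c.requires else {}),
                    "incidence": copy.deepcopy(c.incidence),
                    "rr": dict(c.rr),
                    "excess_mortality": c.excess_mortality,
                }
                for name, c in params.disease.conditions.items()
            },
        },
        "economics": {
            "source": params.economics.source,
            "discount_rate": params.economics.discount_rate,
            "daily_wage_usd": params.economics.daily_wage_usd,
            "healthy_utility": params.economics.healthy_utility,
            "perspective": params.economics.perspective,
            "conditions": {name: asdict(c)
                           for name, c in params.economics.conditions.items()},
        },
    }
    return out


# ---------------------------------------------------------------------------
# loading


def default_config_dict() -> dict:
    """The packaged default configuration as a plain dict."""
    text = importlib.resources.files("vpop.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in out:
            raise ParamsError(f"unknown config key: {here}")
        if isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_params(path: str | None = None) -> ModelParams:
    """Load a validated :class:`ModelParams`.

    Without a path, the packaged defaults are returned. With a path, the YAML
    (or JSON — YAML is a superset) file is read and deep-merged onto the
    defaults, so partial overrides are supported. Invariant violations raise
    :class:`ParamsError` naming the first offending field.
    """
    cfg = default_config_dict()
    if path is not None:
        try:
            with open(path) as fh:
                user = yaml.safe_load(fh)
        except OSError as exc:
            raise ParamsError(f"cannot read parameter file {path!r}: {exc}") from exc
        if user:
            cfg = _deep_merge(cfg, user)
    params = params_from_dict(cfg)
    violations = validate_params(params)
    if violations:
        raise ParamsError(
            "invalid parameters:\n" + "\n".join(f"  - {v}" for v in violations))
    return params


def write_params(params: ModelParams, path: str) -> None:
    """Serialise a parameter bundle to YAML; round-trips through load_params."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# validation


def validate_params(params: ModelParams) -> list[Violation]:
    """Check every domain invariant; an empty list means the bundle is valid."""
    out: list[Violation] = []

    def check(ok: bool, fieldname: str, value, rule: str):
        if not ok:
            out.append(Violation(fieldname, value, rule))

    n_strata = sum(1 for s in SEXES for g in AGE_GROUPS
                   if g in params.demography.counts.get(s, {}))
    check(n_strata == 4, "demography.counts", n_strata, "exactly 4 strata")
    for s, g in STRATA:
        c = params.demography.counts[s][g]
        check(c > 0, f"demography.counts.{s}.{g}", c, "count > 0")

    act = params.activity
    for s, g in STRATA:
        d = act.active_days[s][g]
        check(0.0 <= d.mean <= 7.0, f"activity.active_days.{s}.{g}.mean", d.mean,
              "0 <= mean days <= 7")
        check(d.sd >= 0.0, f"activity.active_days.{s}.{g}.sd", d.sd, "SD >= 0")
    for s in SEXES:
        im = act.intensity_met[s]
        check(im.mean > 1.0, f"activity.intensity_met.{s}.mean", im.mean, "MET mean > 1")
        check(im.sd >= 0.0, f"activity.intensity_met.{s}.sd", im.sd, "SD >= 0")
        mins_a = act.active_day_minutes[s]
        mins_n = act.nonactive_day_minutes[s]
        check(mins_a >= 0.0, f"activity.active_day_minutes.{s}", mins_a, "minutes >= 0")
        check(0.0 <= mins_n <= mins_a, f"activity.nonactive_day_minutes.{s}", mins_n,
              "non-PA-day minutes in [0, active-day minutes]")

    for s in SEXES:
        pr = params.sports.participation[s]
        check(0.0 <= pr <= 1.0, f"sports.participation.{s}", pr, "probability in [0, 1]")
        mv = params.sports.mvpa_min_per_week[s]
        check(mv >= 0.0, f"sports.mvpa_min_per_week.{s}", mv, "MVPA >= 0")
        tri = params.sports.intensity_met[s]
        check(tri.min <= tri.mean <= tri.max, f"sports.intensity_met.{s}",
              (tri.min, tri.mean, tri.max), "MET range brackets the mean")

    bc = params.body_composition
    check(bc.fat_mass_interpretation in ("kg", "ratio"),
          "body_composition.fat_mass_interpretation", bc.fat_mass_interpretation,
          "one of {'kg', 'ratio'}")
    for block_name, block in [("fat_free_mass_kg", bc.fat_free_mass_kg),
                              ("fat_mass", bc.fat_mass)]:
        for s, g in STRATA:
            v = block[s][g]
            check(v.mean > 0.0, f"body_composition.{block_name}.{s}.{g}.mean", v.mean,
                  "mean > 0")
            check(v.sd >= 0.0, f"body_composition.{block_name}.{s}.{g}.sd", v.sd, "SD >= 0")

    pt = params.prevalence_targets
    for s, g in STRATA:
        ow, ob = pt.overweight_pct[s][g], pt.obesity_pct[s][g]
        check(ow.mean + ob.mean < 100.0, f"prevalence_targets.{s}.{g}",
              (ow.mean, ob.mean), "overweight + obesity < 100%")
        for nm, v in [("overweight_pct", ow), ("obesity_pct", ob)]:
            check(v.lo <= v.mean <= v.hi, f"prevalence_targets.{nm}.{s}.{g}",
                  (v.lo, v.mean, v.hi), "mean within its CI bounds")

    met = params.metabolic
    for nm in ("rho_fat_kcal_per_kg", "rho_lean_kcal_per_kg", "forbes_c_kg",
               "kcal_per_kg_met_min", "fat_mass_floor_kg", "fat_free_mass_floor_kg"):
        v = getattr(met, nm)
        check(v > 0.0, f"metabolic.{nm}", v, "> 0")
    check(met.growth_kcal_per_day_minor >= 0.0, "metabolic.growth_kcal_per_day_minor",
          met.growth_kcal_per_day_minor, ">= 0")
    check(met.rho_fat_kcal_per_kg > met.rho_lean_kcal_per_kg,
          "metabolic.rho_fat_kcal_per_kg", met.rho_fat_kcal_per_kg,
          "fat energy density > fat-free energy density")

    dis = params.disease
    check(dis.max_age > 18, "disease.max_age", dis.max_age, "max age > 18")
    check(dis.gompertz_a > 0.0, "disease.background_mortality.gompertz_a",
          dis.gompertz_a, "> 0 (forced to 1 at max age)")
    check(dis.gompertz_b >= 0.0, "disease.background_mortality.gompertz_b",
          dis.gompertz_b, ">= 0")
    for name, c in dis.conditions.items():
        for s in SEXES:
            for band, q in c.incidence[s].items():
                check(0.0 <= q <= 1.0, f"disease.conditions.{name}.incidence.{s}.{band}",
                      q, "probability in [0, 1]")
        for cat, rr in c.rr.items():
            check(rr > 0.0, f"disease.conditions.{name}.rr.{cat}", rr, "relative risk > 0")
        check(0.0 <= c.excess_mortality <= 1.0,
              f"disease.conditions.{name}.excess_mortality", c.excess_mortality,
              "probability in [0, 1]")
        if c.requires is not None:
            check(c.requires in dis.conditions, f"disease.conditions.{name}.requires",
                  c.requires, "must name another condition")

    econ = params.economics
    check(0.0 <= econ.discount_rate < 1.0, "economics.discount_rate",
          econ.discount_rate, "0 <= rate < 1")
    check(econ.daily_wage_usd >= 0.0, "economics.daily_wage_usd", econ.daily_wage_usd,
          "wage >= 0")
    check(0.0 <= econ.healthy_utility <= 1.0, "economics.healthy_utility",
          econ.healthy_utility, "utility in [0, 1]")
    check(econ.perspective in ("societal", "third_party"), "economics.perspective",
          econ.perspective, "one of {'societal', 'third_party'}")
    for name in dis.conditions:
        if name not in econ.conditions:
            out.append(Violation(f"economics.conditions.{name}", None,
                                 "every disease condition needs a cost/utility entry"))
    for name, c in econ.conditions.items():
        check(c.annual_cost_usd >= 0.0, f"economics.conditions.{name}.annual_cost_usd",
              c.annual_cost_usd, "cost >= 0")
        check(0.0 <= c.utility <= 1.0, f"economics.conditions.{name}.utility",
              c.utility, "utility in [0, 1]")

    return out
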