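"""Synthetic cohort generation calibrated to national prevalence targets.

The cohort emulates the joint structure of the survey-derived initialisation:
four sex-by-age-group strata with population counts apportioned by the
largest-remainder rule, continuous ages uniform within each band, and body
composition (fat-free mass and fat mass) drawn from truncated normal
marginals with the stratum mean/SD of the packaged inputs. Because only
stratum marginals are published, the joint realism is limited; a final
monotone calibration step adjusts each stratum's BMI-for-age z-scores so the
classified overweight and obesity fractions hit the national prevalence
targets, with the implied mass change taken out of (or added to) fat mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dists import truncnorm_ppf
from .growth import CATEGORY_NAMES, SEX_CODE, Z_OBESITY, Z_OVERWEIGHT, GrowthReference, \
    load_growth_reference
from .params import AGE_GROUP_BOUNDS, AGE_GROUPS, SEXES, STRATA, BodyCompositionParams, \
    ModelParams, PrevalenceTargets

#: column dictionary for the cohort table (also the CSV schema)
COHORT_COLUMNS = {
    "id": "integer agent id, unique within the cohort",
    "sex": "male|female",
    "age_group": "entry age band, 6-11 or 12-17",
    "age": "age in years at simulation start (continuous)",
    "ffm_kg": "fat-free mass, kg",
    "fm_kg": "fat mass, kg",
    "height_m": "height, metres (reference median height at entry age)",
    "bmi": "body mass index at entry, kg/m^2",
    "zscore": "BMI-for-age z-score at entry",
    "weight_category": "0 healthy, 1 overweight, 2 obesity (youth percentile cuts)",
    "sports_uniform": "uniform draw behind the sports-participation Bernoulli",
    "sports_participant": "participation flag at the baseline probability",
}


class CalibrationError(Exception):
    pass


@dataclass
class Cohort:
    """Agent table plus the scale linking it to national counts."""

    df: pd.DataFrame
    scale: float
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sex_code(self) -> np.ndarray:
        return self.df["sex"].map(SEX_CODE).to_numpy(np.int8)

    def stratum_mask(self, sex: str, age_group: str) -> np.ndarray:
        return ((self.df["sex"] == sex) & (self.df["age_group"] == age_group)).to_numpy()

    def copy(self) -> "Cohort":
        return Cohort(df=self.df.copy(), scale=self.scale, seed=self.seed)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scale: float, seed: int | None = None) -> "Cohort":
        return cls(df=pd.read_csv(path), scale=scale, seed=seed)


def stratum_counts(params: ModelParams, scale: float) -> dict:
    """Largest-remainder apportionment of ``scale`` x national stratum counts.

    The scaled total is rounded to the nearest integer; each stratum gets the
    floor of its scaled count and the remaining units go to the strata with
    the largest fractional remainders (ties broken by the fixed stratum
    order). At scale 1.0 this reproduces the national counts exactly.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    shares = {key: scale * params.demography.counts[key[0]][key[1]] for key in STRATA}
    total = int(round(sum(shares.values())))
    base = {key: math.floor(v) for key, v in shares.items()}
    rem = total - sum(base.values())
    order = sorted(STRATA, key=lambda k: shares[k] - base[k], reverse=True)
    for key in order[:rem]:
        base[key] += 1
    return base


def sample_body_composition(sex: str, age_group: str, params: BodyCompositionParams,
                            rng: np.random.Generator, ages: np.ndarray | None = None,
                            n: int | None = None,
                            growth_ref: GrowthReference | None = None):
    """Draw (fat-free mass kg, fat mass kg) for one stratum.

    Marginals are normals with the stratum mean/SD, truncated below at zero.
    With ``age_scaling`` enabled (and a growth reference available) the mean
    and SD scale with the reference median body mass across the age band,
    normalised so the stratum marginal mean/SD are unchanged; a fixed stratum
    mean across a six-year band would otherwise give six-year-olds teenage
    masses. Under the ``ratio`` interpretation the fat row is drawn as a
    fat/fat-free ratio and multiplied onto the sampled fat-free mass.
    """
    ffm_ms = params.fat_free_mass_kg[sex][age_group]
    fm_ms = params.fat_mass[sex][age_group]
    for ms, name in [(ffm_ms, "fat_free_mass"), (fm_ms, "fat_mass")]:
        if ms.sd < 0:
            raise ValueError(f"{name} SD must be >= 0, got {ms.sd}")
    if ages is None:
        if n is None:
            raise ValueError("provide ages or n")
        lo, hi = AGE_GROUP_BOUNDS[age_group]
        ages = rng.uniform(lo, hi, n)
    ages = np.asarray(ages, float)
    n = len(ages)

    if params.age_scaling and growth_ref is not None:
        code = SEX_CODE[sex]
        s = growth_ref.median_mass(ages, code) / growth_ref.band_mean_median_mass(code, age_group)
    else:
        s = np.ones(n)

    ffm = truncnorm_ppf(rng.random(n), ffm_ms.mean * s, ffm_ms.sd * s, lo=1e-6)
    if params.fat_mass_interpretation == "ratio":
        ratio = truncnorm_ppf(rng.random(n), fm_ms.mean, fm_ms.sd, lo=1e-6)
        fm = ratio * ffm
    else:
        fm = truncnorm_ppf(rng.random(n), fm_ms.mean * s, fm_ms.sd * s, lo=1e-6)
    return ffm, fm


def build_cohort(params: ModelParams, scale: float, seed: int,
                 growth_ref: GrowthReference | None = None,
                 calibrate: bool = True) -> Cohort:
    """Generate the agent cohort at a fraction ``scale`` of national counts.

    Deterministic given (params, scale, seed). Stratum sizes follow
    :func:`stratum_counts`; ages are uniform within each band; body
    composition comes from :func:`sample_body_composition`; sports
    participation is Bernoulli with the sex-specific probability (the
    underlying uniform is stored so counterfactual participation levels can
    be applied to the same agents). When ``calibrate`` is true the cohort is
    passed through :func:`calibrate_to_prevalence`.
    """
    if growth_ref is None:
        growth_ref = load_growth_reference(params.growth_reference)
    counts = stratum_counts(params, scale)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    frames = []
    next_id = 0
    for sex, group in STRATA:
        n = counts[(sex, group)]
        lo, hi = AGE_GROUP_BOUNDS[group]
        ages = rng.uniform(lo, hi, n)
        ffm, fm = sample_body_composition(sex, group, params.body_composition, rng,
                                          ages=ages, growth_ref=growth_ref)
        code = SEX_CODE[sex]
        height = growth_ref.median_height(ages, code)
        bmi = (ffm + fm) / (height * height)
        z = growth_ref.zscore(ages, code, bmi)
        u_sport = rng.random(n)
        frames.append(pd.DataFrame({
            "id": np.arange(next_id, next_id + n),
            "sex": sex,
            "age_group": group,
            "age": ages,
            "ffm_kg": ffm,
            "fm_kg": fm,
            "height_m": height,
            "bmi": bmi,
            "zscore": z,
            "weight_category": growth_ref.classify(ages, code, bmi),
            "sports_uniform": u_sport,
            "sports_participant": u_sport < params.sports.participation[sex],
        }))
        next_id += n

    cohort = Cohort(df=pd.concat(frames, ignore_index=True), scale=scale, seed=seed)
    if calibrate:
        cohort = calibrate_to_prevalence(cohort, params.prevalence_targets, growth_ref,
                                         metabolic=params.metabolic)
    return cohort


def _affine_z_map(z: np.ndarray, q_ow: float, q_ob: float):
    """Monotone affine map of z-scores hitting the two prevalence targets.

    Maps the empirical (1 - q_ow - q_ob) and (1 - q_ob) quantiles onto the
    85th- and 95th-percentile cut points; both classified fractions then
    match the targets up to quantile interpolation (Monte-Carlo) error.
    """
    q2 = q_ow + q_ob
    if q2 <= 0.0:
        # no one should classify as overweight or obese
        return 1.0, Z_OVERWEIGHT - 1e-6 - float(np.max(z))
    z_lo = float(np.quantile(z, 1.0 - q2))
    if q_ob <= 0.0:
        z_hi = float(np.max(z))
        target_hi = Z_OBESITY - 1e-6
    else:
        z_hi = float(np.quantile(z, 1.0 - q_ob))
        target_hi = Z_OBESITY
    if z_hi - z_lo < 1e-9:
        return 1.0, Z_OVERWEIGHT - z_lo
    a = (target_hi - Z_OVERWEIGHT) / (z_hi - z_lo)
    b = Z_OVERWEIGHT - a * z_lo
    return a, b


def calibrate_to_prevalence(cohort: Cohort, targets: PrevalenceTargets,
                            growth_ref: GrowthReference,
                            metabolic=None) -> Cohort:
    """Monotone stratum-wise recalibration of body mass to prevalence targets.

    Each stratum's BMI-for-age z-scores receive an affine map (rank-
    preserving) chosen so the classified overweight and obesity fractions
    match the targets; the resulting body-mass change is applied to fat mass,
    spilling into fat-free mass only when fat mass reaches its physiologic
    floor. A second application is a near-identity (idempotent up to quantile
    interpolation error).
    """
    df = cohort.df.copy()
    fm_floor = metabolic.fat_mass_floor_kg if metabolic is not None else 0.5
    ffm_floor = metabolic.fat_free_mass_floor_kg if metabolic is not None else 5.0

    for sex, group in STRATA:
        q_ow = targets.overweight_pct[sex][group].mean / 100.0
        q_ob = targets.obesity_pct[sex][group].mean / 100.0
        if q_ow + q_ob >= 1.0:
            raise CalibrationError(
                f"infeasible prevalence targets for {sex} {group}: "
                f"overweight {q_ow:.2%} + obesity {q_ob:.2%} >= 100%")
        mask = ((df["sex"] == sex) & (df["age_group"] == group)).to_numpy()
        if not np.any(mask):
            continue
        code = SEX_CODE[sex]
        ages = df.loc[mask, "age"].to_numpy()
        height = df.loc[mask, "height_m"].to_numpy()
        ffm = df.loc[mask, "ffm_kg"].to_numpy()
        fm = df.loc[mask, "fm_kg"].to_numpy()
        z = growth_ref.zscore(ages, code, (ffm + fm) / height ** 2)

        a, b = _affine_z_map(z, q_ow, q_ob)
        z_new = np.clip(a * z + b, -4.0, 4.0)
        bmi_new = growth_ref.bmi_from_zscore(ages, code, z_new)
        mass_new = bmi_new * height * height

        fm_new = fm + (mass_new - (ffm + fm))
        deficit = np.maximum(fm_floor - fm_new, 0.0)
        fm_new = np.maximum(fm_new, fm_floor)
        ffm_new = np.maximum(ffm - deficit, ffm_floor)

        bmi_final = (ffm_new + fm_new) / height ** 2
        df.loc[mask, "ffm_kg"] = ffm_new
        df.loc[mask, "fm_kg"] = fm_new
        df.loc[mask, "bmi"] = bmi_final
        df.loc[mask, "zscore"] = growth_ref.zscore(ages, code, bmi_final)
        df.loc[mask, "weight_category"] = growth_ref.classify(ages, code, bmi_final)

    return Cohort(df=df, scale=cohort.scale, seed=cohort.seed)


def measured_prevalence(cohort: Cohort) -> pd.DataFrame:
    """Classified overweight/obesity percentages per stratum (and the cohort)."""
    rows = []
    for sex, group in STRATA:
        mask = cohort.stratum_mask(sex, group)
        cat = cohort.df.loc[mask, "weight_category"].to_numpy()
        n = mask.sum()
        rows.append({
            "sex": sex, "age_group": group, "n": int(n),
            "overweight_pct": 100.0 * float(np.mean(cat == 1)) if n else np.nan,
            "obesity_pct": 100.0 * float(np.mean(cat == 2)) if n else np.nan,
        })
    return pd.DataFrame(rows)
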