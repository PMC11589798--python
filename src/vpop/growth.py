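"""BMI-for-age growth reference and weight-status classification.

The reference is an LMS table (Box-Cox power L, median M, coefficient of
variation S by age and sex) plus a median-height-by-age column. BMI maps to
an age- and sex-standardised z-score via

    z = ((bmi / M)**L - 1) / (L * S)

and the percentile is the normal CDF of z. The packaged table
(``data/growth_reference_synthetic.csv``) is synthetic — smooth, CDC-like
curves with realistic medians and spread — and any real LMS reference in the
same column layout can be substituted through the ``growth_reference`` config
key.

Classification follows the usual convention: for youths (< 18 y) overweight
is the 85th-94th BMI-for-age percentile and obesity the 95th and above; for
adults, BMI 25-29.9 and >= 30.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .params import AGE_GROUP_BOUNDS, SEXES

#: z-score cut points implied by the 85th / 95th percentile convention
Z_OVERWEIGHT = float(ndtri(0.85))
Z_OBESITY = float(ndtri(0.95))
ADULT_BMI_OVERWEIGHT = 25.0
ADULT_BMI_OBESITY = 30.0

#: integer codes used throughout the vectorised kernels
SEX_CODE = {"male": 0, "female": 1}
CATEGORY_NAMES = ("healthy", "overweight", "obesity")


class GrowthReferenceError(Exception):
    pass


@dataclass
class _SexCurves:
    age: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    height: np.ndarray


class GrowthReference:
    """Interpolated LMS BMI-for-age curves with their inverse, per sex."""

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age_years", "L", "M", "S", "median_height_m"}
        missing = required - set(table.columns)
        if missing:
            raise GrowthReferenceError(f"growth reference missing columns: {sorted(missing)}")
        self._curves = {}
        for sex in SEXES:
            sub = table[table["sex"] == sex].sort_values("age_years")
            if sub.empty:
                raise GrowthReferenceError(f"growth reference has no rows for sex {sex!r}")
            self._curves[SEX_CODE[sex]] = _SexCurves(
                age=sub["age_years"].to_numpy(float),
                L=sub["L"].to_numpy(float),
                M=sub["M"].to_numpy(float),
                S=sub["S"].to_numpy(float),
                height=sub["median_height_m"].to_numpy(float),
            )
        self.age_min = max(c.age[0] for c in self._curves.values())
        self.age_max = min(c.age[-1] for c in self._curves.values())
        self._build_fast_tables()

    def _build_fast_tables(self) -> None:
        """Stack per-sex curves for O(1) uniform-grid interpolation.

        Only possible when both sexes share one uniformly spaced age grid
        (true for the packaged table); otherwise lookups fall back to
        ``np.interp`` per sex.
        """
        male, female = self._curves[0], self._curves[1]
        self._uniform = False
        if male.age.shape == female.age.shape and np.allclose(male.age, female.age):
            steps = np.diff(male.age)
            if len(steps) and np.allclose(steps, steps[0]):
                self._age0 = float(male.age[0])
                self._step = float(steps[0])
                self._n_grid = len(male.age)
                self._tab = {attr: np.stack([getattr(male, attr), getattr(female, attr)])
                             for attr in ("L", "M", "S", "height")}
                self._uniform = True

    @classmethod
    def from_csv(cls, path: str) -> "GrowthReference":
        return cls(pd.read_csv(path))

    @classmethod
    def packaged(cls) -> "GrowthReference":
        """The packaged synthetic reference."""
        with importlib.resources.files("vpop.data").joinpath(
                "growth_reference_synthetic.csv").open() as fh:
            return cls(pd.read_csv(fh))

    # -- interpolation helpers ------------------------------------------------

    def _interp(self, age, sex_code, attr) -> np.ndarray:
        age = np.asarray(age, float)
        sex_code = np.asarray(sex_code)
        if self._uniform:
            pos = np.clip((age - self._age0) / self._step, 0.0,
                          self._n_grid - 1.000001)
            sex_b, pos_b = np.broadcast_arrays(sex_code, pos)
            i0 = pos_b.astype(np.intp)
            frac = pos_b - i0
            tab = self._tab[attr]
            v0 = tab[sex_b, i0]
            return v0 + frac * (tab[sex_b, i0 + 1] - v0)
        out = np.empty(np.broadcast(age, sex_code).shape, float)
        age_b, sex_b = np.broadcast_arrays(age, sex_code)
        for code, curves in self._curves.items():
            mask = sex_b == code
            if np.any(mask):
                out[mask] = np.interp(age_b[mask], curves.age, getattr(curves, attr))
        return out

    def lms(self, age, sex_code):
        return (self._interp(age, sex_code, "L"),
                self._interp(age, sex_code, "M"),
                self._interp(age, sex_code, "S"))

    def median_height(self, age, sex_code) -> np.ndarray:
        """Median height in metres; constant beyond the table's age range."""
        return self._interp(age, sex_code, "height")

    def median_bmi(self, age, sex_code) -> np.ndarray:
        return self._interp(age, sex_code, "M")

    def median_mass(self, age, sex_code) -> np.ndarray:
        """Median body mass (kg) implied by median BMI and median height."""
        h = self.median_height(age, sex_code)
        return self.median_bmi(age, sex_code) * h * h

    # -- z-scores and percentiles --------------------------------------------

    def _check_age(self, age) -> None:
        age = np.asarray(age, float)
        if np.any(age < self.age_min - 1e-9) or np.any(age > self.age_max + 1e-9):
            raise GrowthReferenceError(
                f"age outside reference support [{self.age_min}, {self.age_max}]")

    def zscore(self, age, sex_code, bmi) -> np.ndarray:
        self._check_age(age)
        L, M, S = self.lms(age, sex_code)
        bmi = np.asarray(bmi, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(np.abs(L) > 1e-12,
                         ((bmi / M) ** L - 1.0) / (L * S),
                         np.log(bmi / M) / S)
        return z

    def bmi_from_zscore(self, age, sex_code, z) -> np.ndarray:
        self._check_age(age)
        L, M, S = self.lms(age, sex_code)
        z = np.asarray(z, float)
        base = 1.0 + L * S * z
        # for L < 0 the LMS transform has a finite supremum; stay inside it
        base = np.maximum(base, 1e-6)
        bmi = np.where(np.abs(L) > 1e-12, M * base ** (1.0 / L), M * np.exp(S * z))
        return bmi

    def bmi_percentile(self, age, sex_code, bmi) -> np.ndarray:
        """Percentile in (0, 1); strictly increasing in BMI at fixed age."""
        return ndtr(self.zscore(age, sex_code, bmi))

    def bmi_from_percentile(self, age, sex_code, p) -> np.ndarray:
        return self.bmi_from_zscore(age, sex_code, ndtri(np.asarray(p, float)))

    # -- classification --------------------------------------------------------

    def classify(self, age, sex_code, bmi) -> np.ndarray:
        """Weight-category codes (0 healthy, 1 overweight, 2 obesity).

        Youths (< 18 y) are classified on BMI-for-age percentile (85th/95th);
        adults on absolute BMI (25 / 30).
        """
        age = np.asarray(age, float)
        bmi = np.asarray(bmi, float)
        sex_code = np.asarray(sex_code)
        age_b, sex_b, bmi_b = np.broadcast_arrays(age, sex_code, bmi)
        out = np.zeros(age_b.shape, dtype=np.int8)
        youth = age_b < 18.0
        if np.any(youth):
            z = self.zscore(np.clip(age_b[youth], self.age_min, self.age_max),
                            sex_b[youth], bmi_b[youth])
            out[youth] = np.where(z >= Z_OBESITY, 2, np.where(z >= Z_OVERWEIGHT, 1, 0))
        adult = ~youth
        if np.any(adult):
            b = bmi_b[adult]
            out[adult] = np.where(b >= ADULT_BMI_OBESITY, 2,
                                  np.where(b >= ADULT_BMI_OVERWEIGHT, 1, 0))
        return out

    def band_mean_median_mass(self, sex_code: int, age_group: str, n_grid: int = 97) -> float:
        """Average of the median body mass over an age band (uniform ages)."""
        lo, hi = AGE_GROUP_BOUNDS[age_group]
        grid = np.linspace(lo, min(hi, self.age_max), n_grid)
        return float(np.mean(self.median_mass(grid, sex_code)))


def load_growth_reference(path: str | None = None) -> GrowthReference:
    """Load a growth reference from a CSV path, or the packaged synthetic one."""
    if path is None:
        return GrowthReference.packaged()
    return GrowthReference.from_csv(path)


def classify_weight_status(age, sex_code, bmi, ref: GrowthReference):
    """Functional alias for :meth:`GrowthReference.classify`."""
    return ref.classify(age, sex_code, bmi)
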