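"""Regenerate the packaged synthetic growth reference.

Produces ``src/vpop/data/growth_reference_synthetic.csv``: an LMS-style
(BMI-for-age location/scale/skew) table plus median height by age and sex,
sampled at quarter-year steps over ages 2-20. The curves are smooth
(monotone PCHIP through hand-set anchors) and deliberately CDC-*like*:
medians, spreads and the adult-boundary consistency (the 85th/95th youth
percentiles at age 18 land near BMI 25/30) are realistic, but the table is
synthetic and carries no survey provenance. A genuine LMS reference in the
same column layout drops in via the ``growth_reference`` config key.

Run from the repository root::

    python scripts/make_growth_reference.py
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "vpop" / "data"

ANCHOR_AGES = np.arange(2.0, 21.0)

# BMI-for-age median (M) anchors, kg/m^2
M_MALE = [16.6, 16.1, 15.8, 15.5, 15.4, 15.5, 15.8, 16.2, 16.6, 17.2,
          17.8, 18.4, 19.1, 19.7, 20.3, 20.9, 21.5, 22.0, 22.5]
M_FEMALE = [16.4, 15.9, 15.6, 15.3, 15.2, 15.4, 15.8, 16.3, 16.8, 17.5,
            18.2, 18.9, 19.6, 20.1, 20.6, 21.0, 21.3, 21.5, 21.7]

# Coefficient of variation (S) anchors — spread widens through puberty
S_AGES = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0])
S_MALE = [0.080, 0.080, 0.090, 0.105, 0.120, 0.130, 0.135, 0.135, 0.135, 0.135]
S_FEMALE = [0.085, 0.085, 0.095, 0.110, 0.125, 0.135, 0.140, 0.140, 0.140, 0.140]

# Box-Cox power (L): right-skewed BMI, held constant
L_CONST = -2.0

# Median height anchors, metres
H_MALE = [0.87, 0.96, 1.03, 1.10, 1.16, 1.22, 1.28, 1.34, 1.39, 1.44,
          1.49, 1.56, 1.64, 1.70, 1.74, 1.755, 1.765, 1.77, 1.77]
H_FEMALE = [0.86, 0.95, 1.02, 1.09, 1.15, 1.21, 1.27, 1.33, 1.38, 1.45,
            1.51, 1.57, 1.60, 1.62, 1.628, 1.632, 1.635, 1.635, 1.635]


def main() -> None:
    ages = np.arange(2.0, 20.0 + 1e-9, 0.25)
    rows = []
    for sex, m_anchor, s_anchor, h_anchor in [
        ("male", M_MALE, S_MALE, H_MALE),
        ("female", M_FEMALE, S_FEMALE, H_FEMALE),
    ]:
        m = PchipInterpolator(ANCHOR_AGES, m_anchor)(ages)
        s = PchipInterpolator(S_AGES, s_anchor)(ages)
        h = PchipInterpolator(ANCHOR_AGES, h_anchor)(ages)
        for a, mi, si, hi in zip(ages, m, s, h):
            rows.append({
                "sex": sex,
                "age_years": round(float(a), 2),
                "L": L_CONST,
                "M": round(float(mi), 4),
                "S": round(float(si), 5),
                "median_height_m": round(float(hi), 4),
            })
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "growth_reference_synthetic.csv", index=False)
    print(f"wrote {OUT / 'growth_reference_synthetic.csv'} ({len(df)} rows)")


if __name__ == "__main__":
    main()
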