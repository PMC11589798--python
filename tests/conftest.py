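import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vpop import load_params
from vpop.growth import GrowthReference, load_growth_reference

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def ref():
    return load_growth_reference()


@pytest.fixture(scope="session")
def flat_ref():
    """A zero-growth reference: constant median BMI, spread and height.

    Under it, holding BMI percentile is the same as holding mass, so the
    maintenance intake must equal resting + activity expenditure exactly.
    """
    rows = []
    for sex in ("male", "female"):
        for age in np.arange(2.0, 20.25, 0.25):
            rows.append({"sex": sex, "age_years": age, "L": -2.0, "M": 20.0,
                         "S": 0.12, "median_height_m": 1.60})
    return GrowthReference(pd.DataFrame(rows))
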