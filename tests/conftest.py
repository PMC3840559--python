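import logging

import numpy as np
import pandas as pd
import pytest

from lexpit import CaseControlDesign, LexpitSpec, Stratum
from lexpit.datasets import gender_design, gender_example_data

logging.getLogger("lexpit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def gender_data() -> pd.DataFrame:
    """Two-stratum gender-only study: all cases plus sampled controls."""
    return gender_example_data()


@pytest.fixture(scope="session")
def gender_design_obj() -> CaseControlDesign:
    return gender_design()


@pytest.fixture(scope="session")
def gender_spec() -> LexpitSpec:
    return LexpitSpec(additive=("female",), multiplicative=(), tau=3.0)


@pytest.fixture()
def small_design() -> CaseControlDesign:
    return CaseControlDesign(
        strata=(
            Stratum(label="a", population_size=1000, n_controls_sampled=50),
            Stratum(label="b", population_size=400, n_controls_sampled=20),
        ),
        tau=2.0,
    )


def make_case_control_frame(rng: np.random.Generator, n: int = 120) -> pd.DataFrame:
    """A small random two-stratum subject table with one covariate."""
    x = rng.binomial(1, 0.5, n).astype(float)
    p = 0.15 + 0.25 * x
    y = (rng.random(n) < p).astype(int)
    stratum = np.where(rng.random(n) < 0.6, "a", "b")
    return pd.DataFrame({"outcome": y, "x": x, "stratum": stratum})
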