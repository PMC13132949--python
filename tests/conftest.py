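import numpy as np
import pandas as pd
import pytest

from bpcentile.engines import load_packaged_reference
from bpcentile.prep import prepare_cohort
from bpcentile.synthetic import GeneratorConfig, generate_cohort, make_growth_reference


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_children=400, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def growth_ref(small_config):
    return make_growth_reference(small_config, "height")


@pytest.fixture(scope="session")
def bmi_ref(small_config):
    return make_growth_reference(small_config, "bmi")


@pytest.fixture(scope="session")
def prepared_small(small_cohort, bmi_ref):
    return prepare_cohort(small_cohort, bmi_ref)


@pytest.fixture(scope="session")
def danish_lookup():
    return load_packaged_reference("danish_2025")


@pytest.fixture(scope="session")
def flat_lms_table():
    """Constant L=1, M=20, S=0.1 table over ages 4..18, both sexes."""
    rows = [
        {"sex": s, "age_years": a, "L": 1.0, "M": 20.0, "S": 0.1}
        for s in ("F", "M") for a in range(4, 19)
    ]
    return pd.DataFrame(rows)


def mean_last_two(df, outcome):
    """Vectorised protocol mean for fully-tripled synthetic cohorts."""
    return (df[f"{outcome}2"].to_numpy() + df[f"{outcome}3"].to_numpy()) / 2.0
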