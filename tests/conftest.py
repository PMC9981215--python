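import numpy as np
import pytest

from panmyeloid import default_schema
from panmyeloid.synthetic import SyntheticConfig, generate_cohort, scaled_config


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort(schema):
    """A scaled-down synthetic cohort shared by read-only tests."""
    records, truth = generate_cohort(scaled_config(0.25), seed=11, schema=schema)
    return records, truth


@pytest.fixture(scope="session")
def midsize_cohort(schema):
    """Half-scale cohort for embedding tests (n ~ 600)."""
    records, truth = generate_cohort(scaled_config(0.5), seed=7, schema=schema)
    return records, truth
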