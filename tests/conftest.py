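import numpy as np
import pandas as pd
import pytest

from caresim import (
    GeneratorConfig,
    PipelineConfig,
    default_truth,
    fit_models,
)
from caresim.core import CONDITIONS, empty_population


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def small_config():
    """Small, fast pipeline configuration for integration-style tests."""
    return PipelineConfig(
        generator=GeneratorConfig(population_size=400, seed=7),
        horizon_years=6,
        cognitive_survey_n=1500,
        frailty_survey_n=900,
        claims_n=1500,
        n_bootstrap=3,
    )


@pytest.fixture(scope="session")
def fitted_small(small_config):
    return fit_models(small_config, seed=5)


def make_population(n, rng=None, age_low=60, age_high=95):
    """Random but schema-valid population frame for unit tests."""
    rng = rng or np.random.default_rng(0)
    df = empty_population(n)
    df["id"] = np.arange(n)
    df["age"] = rng.integers(age_low, age_high + 1, size=n).astype(float)
    df["female"] = rng.integers(0, 2, size=n).astype(np.int8)
    df["education"] = rng.integers(0, 3, size=n).astype(np.int8)
    for c in CONDITIONS:
        df[c] = (rng.random(n) < 0.2).astype(np.int8)
    df["adl_limited"] = rng.integers(0, 3, size=n).astype(np.int8)
    df["iadl_limited"] = rng.integers(0, 4, size=n).astype(np.int8)
    df["depression"] = (rng.random(n) < 0.1).astype(np.int8)
    return df


@pytest.fixture
def population():
    return make_population(500)
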