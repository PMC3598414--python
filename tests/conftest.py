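import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from delibank.synthetic import (
    CohortSpec,
    DimensionSpec,
    ResponseMatrix,
    default_cohort_spec,
    generate_truth,
    simulate_responses,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_truth():
    return generate_truth(default_cohort_spec(), seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_truth):
    return simulate_responses(default_truth, 4598, seed=2)


@pytest.fixture(scope="session")
def one_factor_truth():
    spec = CohortSpec(
        dimensions=[
            DimensionSpec("d1", 1, "direct", 10, a_range=(0.8, 2.5), b_range=(-0.5, 2.5))
        ]
    )
    return generate_truth(spec, seed=7)


@pytest.fixture(scope="session")
def one_factor_cohort(one_factor_truth):
    return simulate_responses(one_factor_truth, 4598, seed=8)


@pytest.fixture(scope="session")
def two_factor_truth():
    spec = CohortSpec(
        dimensions=[
            DimensionSpec("d1", 1, "direct", 6, a_range=(1.2, 2.0), b_range=(-0.5, 1.5)),
            DimensionSpec("d2", 2, "direct", 6, a_range=(1.2, 2.0), b_range=(-0.5, 1.5)),
        ],
        corr_between_feature=0.3,
    )
    return generate_truth(spec, seed=5)


@pytest.fixture(scope="session")
def two_factor_cohort(two_factor_truth):
    return simulate_responses(two_factor_truth, 4598, seed=6)


def bernoulli_matrix(n=2000, k=10, p=0.5, seed=0, prefix="i"):
    """Independent Bernoulli columns: association-free reference data."""
    rng = np.random.default_rng(seed)
    y = (rng.random((n, k)) < p).astype(float)
    return ResponseMatrix(
        pd.DataFrame(y, columns=[f"{prefix}{j}" for j in range(k)])
    )
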