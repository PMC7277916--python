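import numpy as np
import pandas as pd
import pytest

from rnaconcord import (
    Cohort,
    CountMatrix,
    load_breast_cohort,
    load_lung_cohort,
)


@pytest.fixture(scope="session")
def bc_cohort() -> Cohort:
    return load_breast_cohort()


@pytest.fixture(scope="session")
def lc_cohort() -> Cohort:
    return load_lung_cohort()


@pytest.fixture(scope="session")
def combined_cohort(bc_cohort, lc_cohort) -> Cohort:
    return Cohort.concat(bc_cohort, lc_cohort)


@pytest.fixture
def small_matrix() -> CountMatrix:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 500, size=(50, 10))
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"g{i:02d}" for i in range(50)],
            columns=[f"s{j}" for j in range(10)],
        )
    )
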