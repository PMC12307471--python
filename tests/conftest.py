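import numpy as np
import pytest

from serfe import (
    FeatureMatrix,
    SyntheticCohortSpec,
    generate_cohort,
    generate_tumor_volume,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng):
    values = rng.standard_normal((12, 6))
    return FeatureMatrix(
        [f"p{i}" for i in range(12)],
        [f"f{j}" for j in range(6)],
        values,
        labels=np.array([0, 1] * 6),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seeded)."""
    return generate_cohort(SyntheticCohortSpec(seed=7))


@pytest.fixture(scope="session")
def tumor_roi():
    return generate_tumor_volume(seed=3, grid_size=32)
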