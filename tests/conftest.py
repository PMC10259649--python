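import numpy as np
import pytest

from moldscore import (
    SyntheticConfig,
    build_default_panel,
    floor_matrix,
    generate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def cohort(panel):
    """Default two-year synthetic cohort, seed 7: (matrix, metadata, truth)."""
    return generate_cohort(SyntheticConfig(seed=7), panel)


@pytest.fixture(scope="session")
def floored_cohort(panel, cohort):
    matrix, metadata, truth = cohort
    return floor_matrix(matrix), metadata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
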