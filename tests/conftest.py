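import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from lnradiomics.synthetic import (
    METASTATIC_PARAMS,
    NORMAL_PARAMS,
    CohortConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """40 + 40 cases with default class parameters, shared across tests."""
    return generate_cohort(CohortConfig(40, 40, seed=123))


@pytest.fixture(scope="session")
def small_study(small_cohort):
    """Pre-extracted features for the shared small cohort."""
    from lnradiomics.pipeline import extract_features

    return extract_features(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_params():
    return {"normal": NORMAL_PARAMS, "metastatic": METASTATIC_PARAMS}
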