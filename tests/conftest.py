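import numpy as np
import pytest

from radgbm.pipeline import cohort_feature_matrix
from radgbm.synth import default_config

COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_cohort():
    """One default 65-patient cohort with its radiomic matrix (shared)."""
    cfg = default_config(seed=COHORT_SEED)
    features, cohort = cohort_feature_matrix(cfg)
    return {"config": cfg, "features": features, "cohort": cohort}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
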