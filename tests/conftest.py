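import numpy as np
import pytest

from miscbias import cohort as coh
from miscbias import pipeline as pipe

#: fixed seed prescribed for the scaled-down acceptance study
ACCEPTANCE_SEED = 0


def tiny_spec(seed: int = 0, n_incontinent: int = 60, n_continent: int = 50,
              n_none: int = 4000) -> coh.CohortSpec:
    """Small cohort for fast unit tests: default generative structure,
    shrunken class counts."""
    spec = coh.default_spec(seed=seed)
    spec.n_incontinent = n_incontinent
    spec.n_continent = n_continent
    spec.n_none = n_none
    return spec


@pytest.fixture(scope="session")
def tiny_table():
    return coh.generate_cohort(tiny_spec(seed=11))


@pytest.fixture(scope="session")
def study():
    """Full scaled-down study used by the acceptance tests
    (~50k rows, case counts preserved, 200 bootstraps, fixed seed)."""
    return pipe.run_study(pipe.test_config(seed=ACCEPTANCE_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
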