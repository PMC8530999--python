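import numpy as np
import pytest

import boldpls as bp
from boldpls.cohort import behavior_matrix


@pytest.fixture(scope="session")
def default_cohort():
    return bp.generate_cohort(bp.CohortSpec(seed=0))


@pytest.fixture(scope="session")
def planted_study():
    """Moderate-size synthetic study with a planted component (es=0.5)."""
    cohort = bp.generate_cohort(bp.CohortSpec(seed=1))
    truth = bp.default_truth(500, effect_size=0.5, seed=2)
    X, latent = bp.generate_variability_maps(cohort, truth, 500, noise_sd=1.0, seed=3)
    Y = behavior_matrix(cohort)
    return cohort, X, Y, truth, latent


@pytest.fixture(scope="session")
def fitted_model(planted_study):
    cohort, X, Y, truth, _ = planted_study
    return bp.PLSCorrelation().fit(X, Y)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
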