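import numpy as np
import pytest

from ipfpvol.synth import CohortSpec, generate_cohort

#: canonical index of the planted generating variables in FEATURE_NAMES order
PLANTED_SUBSET = ("age", "gender", "bmi", "adipsin/CRP")


@pytest.fixture(scope="session")
def planted_cohort():
    """n=1000 cohort whose volume is a known function of the planted subset."""
    return generate_cohort(CohortSpec(n_subjects=1000, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n_subjects=200, seed=3))


@pytest.fixture()
def noiseless_spec():
    """Planted generator with no noise: volume is exactly linear in truth."""
    return CohortSpec(n_subjects=400, noise_sd=0.0, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
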