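import numpy as np
import pytest

from lemnopt import (
    GrowthParams,
    REFERENCE_PARAMS,
    REFERENCE_VANDYCK_PARAMS,
)
from lemnopt.fitting import fit
from lemnopt.synthetic import NoiseSpec, TrialDesign, generate_trials


@pytest.fixture(scope="session")
def ref_params() -> GrowthParams:
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def vd_params():
    return REFERENCE_VANDYCK_PARAMS


@pytest.fixture(scope="session")
def noise_free_trials(ref_params):
    """Full factorial design simulated exactly (no observation noise)."""
    return generate_trials(ref_params, TrialDesign(), NoiseSpec(0.0, 0.0, 0.0, seed=0))


@pytest.fixture(scope="session")
def noise_free_fit(noise_free_trials):
    """Developed-model fit on the noise-free design (shared: it is slow)."""
    return fit(noise_free_trials, model="developed")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260905)
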