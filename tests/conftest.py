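import numpy as np
import pytest

from prestim_connect import (
    CohortConfig,
    HRFSpec,
    build_basis_set,
    calibrate_infant_hrf,
    generate_cohort,
)


@pytest.fixture(scope="session")
def infant_hrf():
    spec = HRFSpec()
    return calibrate_infant_hrf(spec), spec


@pytest.fixture(scope="session")
def basis(infant_hrf):
    hrf, spec = infant_hrf
    return build_basis_set(hrf, spec.dt)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
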