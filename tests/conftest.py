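import numpy as np
import pytest

from dialypk.model import CovariateSet, derive_individual_parameters
from dialypk.params import default_fixed_effects, default_omega, default_residual
from dialypk.study import StudyDesign, generate_study


@pytest.fixture(scope="session")
def fixed():
    return default_fixed_effects()


@pytest.fixture(scope="session")
def omega():
    return default_omega()


@pytest.fixture(scope="session")
def residual():
    return default_residual()


@pytest.fixture(scope="session")
def nrf_ind(fixed):
    """Population-typical subject with normal renal function (70 kg, eGFR 90)."""
    return derive_individual_parameters(fixed, CovariateSet(weight=70.0, egfr=90.0))


@pytest.fixture(scope="session")
def esrd_ind(fixed):
    """Population-typical ESRD subject (70 kg, eGFR 10)."""
    return derive_individual_parameters(fixed, CovariateSet(weight=70.0, egfr=10.0))


@pytest.fixture(scope="session")
def noise_free_study(fixed, omega):
    """Synthetic Phase I dataset with zero residual error, plus truth ledger."""
    return generate_study(StudyDesign(), fixed, omega, None, seed=11)


@pytest.fixture(scope="session")
def noisy_study(fixed, omega, residual):
    return generate_study(StudyDesign(), fixed, omega, residual, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
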