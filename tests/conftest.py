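import numpy as np
import pytest

from cartmc.data_io import DEFAULT_T0, patient28_dose, patient28_fixture, patient28_initial_kinetics
from cartmc.ode_model import FixedParams, KineticParams


@pytest.fixture(scope="session")
def fixed():
    return FixedParams()


@pytest.fixture(scope="session")
def patient28():
    return patient28_fixture()


@pytest.fixture(scope="session")
def init_kinetics():
    return patient28_initial_kinetics()


@pytest.fixture(scope="session")
def dose():
    return patient28_dose()


@pytest.fixture(scope="session")
def t0():
    return DEFAULT_T0


def random_kinetics(rng: np.random.Generator) -> KineticParams:
    """A random plausible parameter draw for property tests: rates on the
    scale of the literature values, jittered multiplicatively."""
    base = patient28_initial_kinetics().to_array()
    factors = rng.lognormal(mean=0.0, sigma=0.5, size=base.size)
    vals = base * factors
    return KineticParams.from_array(vals)


@pytest.fixture(scope="session")
def ls_patient28(patient28, init_kinetics, fixed, dose, t0):
    """The least-squares fit of the bundled patient, shared across tests
    (it is deterministic and takes ~30 s)."""
    from cartmc.least_squares_fit import fit_least_squares

    return fit_least_squares(patient28, init_kinetics, fixed, dose, t0)
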