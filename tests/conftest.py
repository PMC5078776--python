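import numpy as np
import pytest

from leafgas.fvcb import AciCurve, FvcbParams, KineticConstants, forward_fvcb
from leafgas.synthetic import ACI_CA_SEQUENCE, LeafScenario


@pytest.fixture(scope="session")
def constants() -> KineticConstants:
    return KineticConstants()


@pytest.fixture(scope="session")
def truth_params() -> FvcbParams:
    return FvcbParams(vcmax=100.0, jmax=150.0, rd=1.5, gm=0.3)


@pytest.fixture(scope="session")
def protocol_ci() -> np.ndarray:
    """The 16-step applied-Ca protocol used as a ci evaluation grid."""
    return np.asarray(ACI_CA_SEQUENCE, dtype=float)


@pytest.fixture(scope="session")
def forward_curve(truth_params, constants, protocol_ci) -> AciCurve:
    """Noiseless forward-model curve at the protocol grid."""
    a = forward_fvcb(truth_params, constants, protocol_ci).a
    return AciCurve(ci=protocol_ci, a=a, ca=protocol_ci)


@pytest.fixture()
def quiet_scenario(truth_params) -> LeafScenario:
    """A noise-free synthetic leaf."""
    return LeafScenario(fvcb=truth_params, noise_sd_a=0.0, noise_sd_gs=0.0,
                        artifact=None, seed=0)
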