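import numpy as np
import pytest
from hypothesis import settings

from nfkbloop import reference_params, reference_signal
from nfkbloop.params import ModelParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref():
    """The shipped calibrated reference parameter set."""
    return reference_params()


@pytest.fixture(scope="session")
def ref_signal():
    return reference_signal()


@pytest.fixture(scope="session")
def simple_params():
    """A small, fast, weakly damped single-loop configuration for unit tests."""
    return ModelParams(
        nf_tot=125.0, c0=0.00185, c1=18.0, deg_a=0.12, r_ikk=0.12, rho=1.0,
        kp=30.0, kc=2.0, tau1=40.0, tau2=45.0, eps=0.0, c0_e=0.0002, deg_e=0.05,
    )
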