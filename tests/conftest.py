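import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import liverkin as lk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ifp() -> lk.InputFunctionParams:
    return lk.InputFunctionParams()


@pytest.fixture(scope="session")
def arterial(ifp):
    return lk.simulate_arterial_input(ifp)


@pytest.fixture(scope="session")
def portal(ifp, arterial):
    return lk.simulate_portal_input(arterial, ifp.tau_pv_s)


@pytest.fixture(scope="session")
def short_schedule() -> lk.FrameSchedule:
    return lk.make_schedule("short_term")


@pytest.fixture(scope="session")
def full_schedule() -> lk.FrameSchedule:
    return lk.make_schedule("full_dynamic")


@pytest.fixture(scope="session")
def hcc_params() -> lk.KineticParams:
    """Published HCC-group mean kinetic parameters (combined model)."""
    return lk.KineticParams(k1=1.52, k2=1.84, k3=0.046, k4=0.021, hpi=0.764, vb=0.052)


@pytest.fixture(scope="session")
def liver_params() -> lk.KineticParams:
    """Published background-liver mean kinetic parameters (combined model)."""
    return lk.KineticParams(k1=1.00, k2=1.01, k3=0.005, k4=0.023, hpi=0.4276, vb=0.01)


@pytest.fixture(scope="session")
def hcc_subject_noiseless(hcc_params, ifp, short_schedule) -> lk.SubjectData:
    return lk.simulate_subject(hcc_params, ifp, short_schedule, noise_cv=0.0)
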