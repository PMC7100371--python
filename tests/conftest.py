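import logging

import pytest

from lidkin import DelaySchedule, KineticParams


@pytest.fixture(autouse=True)
def _quiet_classifier_warnings(caplog):
    # rare Poisson-driven doublet misclassifications are logged; keep test
    # output readable but still capture records for assertions
    logging.getLogger("lidkin.fragments").setLevel(logging.ERROR)
    yield
    logging.getLogger("lidkin.fragments").setLevel(logging.NOTSET)


@pytest.fixture
def default_params() -> KineticParams:
    return KineticParams()


@pytest.fixture
def fast_params() -> KineticParams:
    """Recovery-friendly ground truth at reduced counting noise."""
    return KineticParams(tau1=200e-9, tau2=800e-6, n0=2000.0)


@pytest.fixture
def small_schedule() -> DelaySchedule:
    return DelaySchedule(n_delays=40, n_repeats=20, n_negative=3)
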