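import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from asgm_hg import (
    BoxModelParams,
    DoseResponseParams,
    calibrated_world,
    run_pipeline,
)


@pytest.fixture(scope="session")
def box_params():
    return BoxModelParams.default()


@pytest.fixture(scope="session")
def unit_dr():
    """Unit-valued dose-response coefficients for hand-checkable arithmetic."""
    return DoseResponseParams(beta=1.0, lambda_=1.0, gamma=1.0, phi=1.0, omega=1.0)


@pytest.fixture(scope="session")
def anchor_world():
    return calibrated_world(seed=0)


@pytest.fixture(scope="session")
def anchor_result(anchor_world):
    """One shared end-to-end run on the anchored synthetic world."""
    return run_pipeline(anchor_world)
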