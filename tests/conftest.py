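import numpy as np
import pytest

from loomsim import ApproachSpec, NPsiParams, make_stimulus


@pytest.fixture(scope="session")
def default_spec():
    """Standard approach: l/v = 30 ms, collision at 0.5 s."""
    return ApproachSpec.from_l_over_v(0.03)


@pytest.fixture(scope="session")
def default_trace(default_spec):
    return make_stimulus(default_spec, zeta0=0.95, zeta1=0.95)


@pytest.fixture(scope="session")
def raw_trace(default_spec):
    """Same approach with no lowpass filtering (raw optical variables)."""
    return make_stimulus(default_spec, zeta0=0.0, zeta1=0.0)


@pytest.fixture(scope="session")
def default_params():
    return NPsiParams()
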