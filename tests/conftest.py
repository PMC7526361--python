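import numpy as np
import pytest

import umaic
from umaic.specs import with_overrides


@pytest.fixture(scope="session")
def scenario1():
    return umaic.default_scenario(1)


@pytest.fixture(scope="session")
def scenario2():
    return umaic.default_scenario(2)


@pytest.fixture(scope="session")
def arm_a_small(scenario1):
    """A modest IPD arm (n=250) for balancing / estimation tests."""
    spec = with_overrides(scenario1.arm_a, n=250)
    return umaic.simulate_arm(spec, treated=False, rng=np.random.default_rng(11), arm_label="A")


@pytest.fixture(scope="session")
def b_arm_small(scenario1):
    """A modest treated arm (n=200) for publication / reconstruction tests."""
    spec = with_overrides(scenario1.arm_b, n=200)
    return umaic.simulate_arm(spec, treated=True, rng=np.random.default_rng(7), arm_label="B")


@pytest.fixture(scope="session")
def b_arm_default(scenario1):
    """One full-size (n=800) treated arm, the published-trial emulation input."""
    return umaic.simulate_arm(
        scenario1.arm_b, treated=True, rng=np.random.default_rng(42), arm_label="B"
    )
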