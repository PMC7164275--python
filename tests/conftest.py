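import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rhinostat import make_fixture, simulate_batch1, simulate_batch2


@pytest.fixture(scope="session")
def tiny_study():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def paper_scale_study():
    return make_fixture("paper_scale")


@pytest.fixture(scope="session")
def recovery_study():
    return make_fixture("recovery")


@pytest.fixture(scope="session")
def batch1_default():
    """Full first simulation batch at its published defaults (seed 0)."""
    return simulate_batch1(seed=0)


@pytest.fixture(scope="session")
def batch2_default():
    """Full second simulation batch at its published defaults (seed 0)."""
    return simulate_batch2(seed=0)
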