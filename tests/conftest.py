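import pytest

from waterconform import default_spec_limits, macae_fixture
from waterconform.datasets import MEASURANDS


@pytest.fixture(scope="session")
def macae():
    """Reconciled fixture series, keyed by measurand."""
    return {m: macae_fixture(m) for m in MEASURANDS}


@pytest.fixture(scope="session")
def limits():
    return default_spec_limits()
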