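import pytest

from hyentag.ecc import default_code
from hyentag.workflow import default_library


@pytest.fixture(scope="session")
def golay():
    return default_code()


@pytest.fixture(scope="session")
def library25():
    """Validated 25-barcode library shared across tests (build is deterministic)."""
    return default_library(25, rng_seed=0)
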