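import numpy as np
import pytest

from remapnet.geometry import SheetSpec
from remapnet.trials import LatencyConfig


@pytest.fixture(scope="session")
def sheet():
    """Default analysis sheet: 21x21 units spanning +/-50 deg."""
    return SheetSpec()


@pytest.fixture(scope="session")
def small_sheet():
    """Tiny sheet for fast network math checks."""
    return SheetSpec(n_units_per_side=5, span_deg=20.0, sigma_deg=6.0)


@pytest.fixture(scope="session")
def latencies():
    return LatencyConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
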