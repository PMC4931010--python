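import numpy as np
import pytest

from chimeramap.barcodes import BarcodeLayout
from chimeramap.simulate import SimConfig, simulate_library


@pytest.fixture(scope="session")
def layout():
    return BarcodeLayout()


@pytest.fixture(scope="session")
def clean_library():
    """Small zero-error, zero-duplicate library shared across tests."""
    cfg = SimConfig(seed=11, n_read_pairs=2000, error_rate=0.0, duplicate_rate=0.0)
    return simulate_library(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
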