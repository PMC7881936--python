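from pathlib import Path

import numpy as np
import pytest

from avrot import published_model, validity_interval
from avrot.datasets import representative_pairs

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def model():
    return published_model()


@pytest.fixture(scope="session")
def interval(model):
    return validity_interval(model)


@pytest.fixture(scope="session")
def rep_pairs():
    """The 30 published representative (ratio, AVR) pairs."""
    return representative_pairs()


@pytest.fixture(scope="session")
def avr_grid():
    return np.arange(2.0, 61.0, 2.0)


@pytest.fixture(scope="session")
def data_dir():
    return DATA_DIR
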