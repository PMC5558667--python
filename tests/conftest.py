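import numpy as np
import pytest

from bhlhkit.domain_scan import load_profile
from bhlhkit.io_formats import SequenceRecord


@pytest.fixture(scope="session")
def profile():
    return load_profile()


@pytest.fixture(scope="session")
def consensus_protein(profile):
    """A protein embedding the exact canonical domain at offset 40."""
    domain = profile.consensus_sequence(8)
    return SequenceRecord("CONS", "", "A" * 40 + domain + "A" * 30), 41, domain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
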