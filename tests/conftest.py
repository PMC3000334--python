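import numpy as np
import pytest

from barcodiag.seqio import Library, SequenceRecord
from barcodiag.simulate import SimConfig, simulate_library


def make_record(rid, seq, species, **kw):
    return SequenceRecord(id=rid, sequence=seq, species=species, **kw)


@pytest.fixture(scope="session")
def default_library():
    """Default 36-species x 5-member synthetic reference library."""
    lib, truth = simulate_library(SimConfig(seed=1))
    return lib, truth


@pytest.fixture(scope="session")
def paraphyly_library():
    """36-species library with one engineered paraphyly (deep ~2.9% split in
    the penultimate species, the last species nested inside it)."""
    lib, truth = simulate_library(SimConfig(seed=2, plant_paraphyly=True))
    return lib, truth


@pytest.fixture(scope="session")
def small_library():
    """5-species x 4-member library, cheap enough for per-test tree builds."""
    lib, truth = simulate_library(SimConfig(n_species=5, members_per_species=4, seed=7))
    return lib, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length=120, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
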