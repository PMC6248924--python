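import numpy as np
import pytest

from flagellarch.scoring import DEFAULT_SCHEME, reduced_alphabet_scheme
from flagellarch.seqio import MultipleAlignment


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def simple_scheme():
    """Match/mismatch scheme over a reduced alphabet for exhaustive tests."""
    return reduced_alphabet_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_peptide(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


@pytest.fixture(scope="session")
def tiny_msa():
    """Small alignment with a gappy column and an insert column."""
    return MultipleAlignment([
        ("s1", "MKV-LAT"),
        ("s2", "MKVQLAT"),
        ("s3", "MKV-LST"),
        ("s4", "MRV-LAT"),
    ])
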