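import numpy as np
import pytest

from nanobarcode.io_seq import Read
from nanobarcode.primers import MarkerPrimerSet
from nanobarcode.simdata import default_primer_sets


@pytest.fixture
def primer_sets():
    return default_primer_sets()


@pytest.fixture
def cytb_primers(primer_sets):
    return primer_sets[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet),
                                                         length)])


@pytest.fixture
def make_read():
    def _make(seq, read_id="r1", q=20):
        return Read(read_id, seq, [q] * len(seq))
    return _make
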