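import numpy as np
import pytest

from bond.filters import FilterParams
from bond.sequence_store import encode_sequences


@pytest.fixture
def params():
    return FilterParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_store(seqs, ids=None):
    """Encode a list of sequence strings into a store with generated IDs."""
    ids = ids or [f"g{i}" for i in range(len(seqs))]
    return encode_sequences(list(zip(ids, seqs)))


def random_dna(rng, n, gc=0.5):
    return "".join(
        rng.choice(list("ACGT"), size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    )
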