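import numpy as np
import pytest

from promokit import SeqRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length, gc=0.5):
    at = (1 - gc) / 2
    return "".join(
        rng.choice(list("ACGT"), size=length, p=[at, gc / 2, gc / 2, at])
    )


@pytest.fixture
def tiny_records():
    return [
        SeqRecord("a", "ACGTACGTAC", label=1),
        SeqRecord("b", "TTTTAAAACC", label=0),
        SeqRecord("c", "GGGGCCCCAA", label=1),
    ]
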