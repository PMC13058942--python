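import numpy as np
import pytest

from phylofoot.iodata import PromoterRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_promoters(rng, n, length, prefix="s"):
    """I.i.d. uniform-background promoters."""
    return [
        PromoterRecord(
            id=f"{prefix}{i}",
            sequence="".join("ACGT"[b] for b in rng.integers(0, 4, length)),
        )
        for i in range(n)
    ]


def plant_word(record, word, pos):
    s = record.sequence
    record.sequence = s[:pos] + word + s[pos + len(word):]
    return record
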