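import numpy as np
import pytest

from hexaw import make_repeat


@pytest.fixture
def s1():
    """The atc-triplet repeat: pure triplet periodicity, no longer structure."""
    return make_repeat("atc", 100)


@pytest.fixture
def s4():
    """The tttccc repeat: triplet periodicity plus a 6-base period."""
    return make_repeat("tttccc", 50)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_cds_seqs(rng, n, min_codons=2, max_codons=40):
    """Random a/t/c/g sequences with multiple-of-3 length >= 6 (stops allowed)."""
    out = []
    for _ in range(n):
        k = int(rng.integers(min_codons, max_codons + 1))
        out.append("".join(rng.choice(list("atcg"), size=3 * k)))
    return out
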