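import numpy as np
import pytest

from phagekit.genome_core import CircularSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n, gc=0.5):
    bases = []
    for _ in range(n):
        pool = "GC" if rng.random() < gc else "AT"
        bases.append(pool[rng.integers(2)])
    return "".join(bases)


@pytest.fixture
def random_circular(rng):
    def make(n=600, gc=0.5, id="test"):
        return CircularSequence(id=id, residues=random_dna(rng, n, gc), topology="circular")

    return make
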