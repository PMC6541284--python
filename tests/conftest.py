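import numpy as np
import pytest

from mhcoevo.genome_types import Antigen, Chromosome, HostGenome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_genome(*chromosomes) -> HostGenome:
    a, b = chromosomes
    return HostGenome(Chromosome(a), Chromosome(b))


def naive_window_values(bits, m=16):
    """Brute-force window scan: direct bit arithmetic at every offset."""
    values = []
    for o in range(len(bits) - m + 1):
        v = 0
        for k in range(m):
            v = (v << 1) | int(bits[o + k])
        values.append(v)
    return values


def embed_pattern(pattern, length=200, offset=0, m=16, fill=0):
    """Antigen of constant ``fill`` bits with ``pattern`` written at ``offset``."""
    bits = np.full(length, fill, dtype=np.uint8)
    for k in range(m):
        bits[offset + k] = (pattern >> (m - 1 - k)) & 1
    return Antigen(bits, m=m)
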