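"""Mutation operators for hosts and pathogens.

Host MHC genes mutate per reproduction event, either by independent single-bit
flips ("micromutation", the default) or by wholesale replacement with a random
pattern ("macromutation").  The per-molecule rate mu_MHC is converted to the
per-bit rate via

    mu_bit = 1 - (1 - mu_MHC)^(1/m)

so that the probability that at least one of the m bits flips equals mu_MHC.
Copy number evolves by per-gene duplication (an identical copy inserted next to
its source) and deletion, floored at one gene per chromosome.  Pathogen
antigens mutate by independent per-site flips.

Operator conventions, fixed for reproducibility:

* duplication/deletion draws are taken against the gene list as it stood at
  the start of the operation — a fresh duplicate is not itself eligible in the
  same event;
* the one-gene floor is applied after realizing all draws, by retaining one
  uniformly chosen would-be-deleted gene;
* during host reproduction each transmitted chromosome undergoes copy-number
  mutation first, then micro/macro mutation of the resulting genes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genome_types import MHC_BITS, Antigen, Chromosome


def per_bit_rate(mu_MHC: float, m: int = MHC_BITS) -> float:
    """Convert a per-molecule mutation probability to a per-bit probability."""
    if not 0.0 <= mu_MHC <= 1.0:
        raise ValueError(f"mu_MHC must lie in [0, 1]; got {mu_MHC!r}")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError(f"m must be a positive integer; got {m!r}")
    return 1.0 - (1.0 - mu_MHC) ** (1.0 / m)


@dataclasses.dataclass(frozen=True)
class MutationRates:
    """Bundle of all mutation probabilities, with the derived per-bit rate."""

    mu_MHC: float
    mu_bit: float
    mu_A: float
    mu_del: float
    mu_dupl: float

    def __post_init__(self) -> None:
        for name in ("mu_MHC", "mu_bit", "mu_A", "mu_del", "mu_dupl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v!r}")

    @classmethod
    def from_config(cls, config) -> "MutationRates":
        return cls(
            mu_MHC=config.mu_MHC,
            mu_bit=per_bit_rate(config.mu_MHC, config.m),
            mu_A=config.mu_A,
            mu_del=config.mu_del,
            mu_dupl=config.mu_dupl,
        )


def sample_distinct_sites(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct uniform sites out of n, cheap for the typical tiny k.

    Rejection sampling with top-up; falls back to a partial permutation when
    k is a large fraction of n (where rejection would thrash).
    """
    if k <= 0:
        return np.empty(0, dtype=np.int64)
    if k > n:
        raise ValueError("cannot draw more distinct sites than exist")
    if k == 1:
        return rng.integers(0, n, size=1)
    if k == 2:
        a = int(rng.integers(0, n))
        b = int(rng.integers(0, n))
        while b == a:
            b = int(rng.integers(0, n))
        return np.array([a, b], dtype=np.int64)
    if k > n // 2:
        return rng.permutation(n)[:k].astype(np.int64)
    pos = np.unique(rng.integers(0, n, size=k))
    while pos.size < k:
        extra = rng.integers(0, n, size=k - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos.astype(np.int64)


_POW2_CACHE: dict[int, np.ndarray] = {}


def _pow2(m: int) -> np.ndarray:
    if m not in _POW2_CACHE:
        _POW2_CACHE[m] = (1 << np.arange(m - 1, -1, -1, dtype=np.uint32)).astype(
            np.uint32
        )
    return _POW2_CACHE[m]


def micromutate(
    chromosome: Chromosome,
    mu_bit: float,
    rng: np.random.Generator,
    m: int = MHC_BITS,
) -> Chromosome:
    """Flip each bit of each gene independently with probability ``mu_bit``."""
    if mu_bit == 0.0:
        return chromosome
    k = len(chromosome)
    mask = rng.random((k, m)) < mu_bit
    if not mask.any():
        return Chromosome(chromosome.genes.copy())
    flips = (mask.astype(np.uint32) * _pow2(m)).sum(axis=1, dtype=np.uint32)
    return Chromosome(chromosome.genes ^ flips)


def macromutate(
    chromosome: Chromosome,
    mu_MHC: float,
    rng: np.random.Generator,
    m: int = MHC_BITS,
) -> Chromosome:
    """Replace each gene, independently with probability ``mu_MHC``, by a
    uniformly random m-bit pattern."""
    if mu_MHC == 0.0:
        return chromosome
    k = len(chromosome)
    mask = rng.random(k) < mu_MHC
    genes = chromosome.genes.copy()
    n_hit = int(mask.sum())
    if n_hit:
        genes[mask] = rng.integers(0, 1 << m, size=n_hit, dtype=np.uint32)
    return Chromosome(genes)


def copy_number_mutate(
    chromosome: Chromosome,
    mu_dupl: float,
    mu_del: float,
    rng: np.random.Generator,
) -> Chromosome:
    """Per-gene duplication and deletion with the one-gene floor.

    Each gene of the input draws duplication and deletion independently; the
    surviving copy count per gene is 1 + dup - del.  If every gene would be
    lost, one uniformly chosen would-be-deleted gene is retained so the
    chromosome keeps at least one locus.
    """
    k = len(chromosome)
    if mu_dupl == 0.0 and mu_del == 0.0:
        return chromosome
    dup = rng.random(k) < mu_dupl
    dele = rng.random(k) < mu_del
    counts = 1 + dup.astype(np.int64) - dele.astype(np.int64)
    if counts.sum() == 0:
        # every gene deleted, none duplicated: keep one of the deleted genes
        counts[int(rng.integers(0, k))] = 1
    return Chromosome(np.repeat(chromosome.genes, counts))


def mutate_antigen(
    antigen: Antigen, mu_A: float, rng: np.random.Generator
) -> Antigen:
    """Flip each antigen site independently with probability ``mu_A``.

    Returns the input object unchanged when no site flips (antigens are
    immutable, so sharing is safe); otherwise a new antigen with its epitope
    bookkeeping patched incrementally.
    """
    if mu_A == 0.0:
        return antigen
    n_flips = int(rng.binomial(antigen.length, mu_A))
    if n_flips == 0:
        return antigen
    positions = sample_distinct_sites(rng, antigen.length, n_flips)
    return antigen.with_flips(positions)
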