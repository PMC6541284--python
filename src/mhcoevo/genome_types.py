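"""Core value types for bitstring genomes of hosts and pathogens.

Hosts carry MHC genes on one diploid pair of chromosomes; each gene is a
16-bit pattern standing in for the polymorphic peptide-binding region (PBR)
of an MHC molecule.  A pathogen is a single long antigenic bitstring whose
contiguous 16-bit windows are the epitopes a host MHC can present.
"""

from __future__ import annotations

import dataclasses
import json
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

from . import _kernels

#: Number of bits in an MHC peptide-binding region pattern.
MHC_BITS: int = 16

#: Number of distinct MHC patterns representable with :data:`MHC_BITS` bits.
PATTERN_SPACE: int = 1 << MHC_BITS

#: Default antigen length in bits.
ANTIGEN_BITS: int = 6000

# window values are stored as uint16 and presence tables are dense over 2^m
_MAX_M = 16


def pattern_space_size(m: int = MHC_BITS) -> int:
    """Number of distinct m-bit MHC patterns (2^m)."""
    if m < 1:
        raise ValueError("pattern length must be >= 1")
    return 1 << m


def pattern_to_bits(pattern: int, m: int = MHC_BITS) -> np.ndarray:
    """Unpack an integer pattern into a uint8 0/1 array, MSB first."""
    if not 0 <= pattern < (1 << m):
        raise ValueError(f"pattern {pattern} out of range for {m} bits")
    return np.array([(pattern >> (m - 1 - k)) & 1 for k in range(m)], dtype=np.uint8)


def bits_to_pattern(bits: Sequence[int]) -> int:
    """Pack a 0/1 sequence (MSB first) into an integer pattern."""
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return value


@dataclasses.dataclass(frozen=True)
class MHCVariant:
    """A 16-bit peptide-binding-region pattern; identity is by value."""

    pattern: int

    def __post_init__(self) -> None:
        if not 0 <= self.pattern < PATTERN_SPACE:
            raise ValueError(
                f"MHC pattern must lie in [0, {PATTERN_SPACE}); got {self.pattern}"
            )

    @property
    def bits(self) -> np.ndarray:
        return pattern_to_bits(self.pattern)

    def __str__(self) -> str:
        return format(self.pattern, f"0{MHC_BITS}b")


class Chromosome:
    """An ordered list of MHC gene patterns; never shorter than one gene.

    Genes are stored as a uint32 array of pattern values.  Order is preserved
    across generations (a duplicate is inserted next to its source) but
    carries no fitness meaning.
    """

    __slots__ = ("genes",)

    def __init__(self, genes: Sequence[int] | np.ndarray):
        arr = np.asarray(genes, dtype=np.uint32)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("a chromosome must carry at least one gene")
        self.genes = arr

    def __len__(self) -> int:
        return int(self.genes.size)

    def __iter__(self) -> Iterator[int]:
        return iter(self.genes.tolist())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromosome):
            return NotImplemented
        return np.array_equal(self.genes, other.genes)

    def __repr__(self) -> str:
        return f"Chromosome({self.genes.tolist()!r})"

    @property
    def variants(self) -> tuple[MHCVariant, ...]:
        return tuple(MHCVariant(int(g)) for g in self.genes)

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy())


@dataclasses.dataclass
class HostGenome:
    """Diploid MHC genome: one pair of chromosomes."""

    chrom_a: Chromosome
    chrom_b: Chromosome

    def all_genes(self) -> np.ndarray:
        return np.concatenate([self.chrom_a.genes, self.chrom_b.genes])

    def variant_array(self) -> np.ndarray:
        """Sorted unique pattern values across both chromosomes."""
        return np.unique(self.all_genes())

    @property
    def n_unique(self) -> int:
        """N of the fitness function: distinct MHC variants in the genome."""
        return int(self.variant_array().size)

    @property
    def n_loci(self) -> int:
        return len(self.chrom_a) + len(self.chrom_b)


def unique_variants(genome: HostGenome) -> set[int]:
    """Set union of gene patterns over both chromosomes (identity by value)."""
    return set(int(g) for g in genome.all_genes())


class Antigen:
    """A pathogen's antigenic molecule: a fixed-length bitstring.

    The derived quantities — the array of all contiguous m-bit window values
    and a dense boolean presence table over the 2^m pattern space — are what
    the matching machinery actually queries.  Antigens are treated as
    immutable: mutation produces a new object, so unmutated clones can share
    storage freely.
    """

    __slots__ = ("bits", "m", "_w", "_presence")

    def __init__(self, bits: Sequence[int] | np.ndarray, m: int = MHC_BITS):
        arr = np.ascontiguousarray(bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("antigen bits must be one-dimensional")
        if not 1 <= m <= _MAX_M:
            raise ValueError(f"window length m must lie in [1, {_MAX_M}]")
        if arr.size < m:
            raise ValueError(f"antigen must be at least m={m} bits long")
        if arr.size and arr.max() > 1:
            raise ValueError("antigen bits must be 0/1")
        self.bits = arr
        self.m = m
        self._w = _kernels.window_scan(arr, m)
        self._presence: np.ndarray | None = None

    @classmethod
    def random(
        cls, rng: np.random.Generator, length: int = ANTIGEN_BITS, m: int = MHC_BITS
    ) -> "Antigen":
        if length < m:
            raise ValueError(f"antigen length must be >= {m}; got {length}")
        return cls(rng.integers(0, 2, size=length, dtype=np.uint8), m=m)

    @property
    def length(self) -> int:
        return int(self.bits.size)

    def __len__(self) -> int:
        return self.length

    @property
    def window_values(self) -> np.ndarray:
        """Window value at every offset 0..length-m (read-only view)."""
        v = self._w.view()
        v.flags.writeable = False
        return v

    @property
    def epitopes(self) -> frozenset[int]:
        """The set of distinct m-bit windows of the molecule."""
        return frozenset(int(x) for x in np.unique(self._w))

    @property
    def presence(self) -> np.ndarray:
        """Dense boolean membership table over the 2^m pattern space (lazy)."""
        if self._presence is None:
            self._presence = _kernels.presence_from_windows(self._w, self.m)
        return self._presence

    def contains(self, pattern: int) -> bool:
        """True iff ``pattern`` occurs as a contiguous m-bit substring."""
        return bool(self.presence[pattern])

    def __contains__(self, pattern: int) -> bool:
        return self.contains(int(pattern))

    def with_flips(self, positions: np.ndarray) -> "Antigen":
        """New antigen with bits flipped at ``positions`` (sites, 0-based)."""
        new = Antigen.__new__(Antigen)
        new.bits = self.bits.copy()
        new.m = self.m
        new._w = self._w.copy()
        new._presence = None
        _kernels.apply_flips(new.bits, new._w, np.asarray(positions, dtype=np.int64), self.m)
        return new

    def hamming(self, other: "Antigen") -> int:
        """Number of differing sites between two equal-length antigens."""
        if self.length != other.length:
            raise ValueError("antigens must have equal length")
        return int(np.count_nonzero(self.bits != other.bits))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Antigen):
            return NotImplemented
        return self.m == other.m and np.array_equal(self.bits, other.bits)

    def __repr__(self) -> str:
        return f"<Antigen length={self.length} m={self.m}>"


def make_random_antigen(rng: np.random.Generator, length: int = ANTIGEN_BITS) -> Antigen:
    """Draw a uniformly random antigen: each bit i.i.d. 0/1 with probability 1/2."""
    if length < MHC_BITS:
        raise ValueError(f"antigen length must be >= {MHC_BITS}; got {length}")
    return Antigen.random(rng, length=length, m=MHC_BITS)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one coevolution run.

    Defaults are the published operating point of the model: a host
    population of 1000 diploid individuals facing S clonal pathogen species
    of equal population size, 6000-bit antigens scanned by 16-bit MHC
    patterns, 10 pathogen generations per host generation, and the standard
    mutation/duplication/deletion rates.
    """

    N_H: int = 1000            # host population size
    N_P: int = 1000            # per-species pathogen population size
    S: int = 8                 # number of pathogen species
    a: int = ANTIGEN_BITS      # antigen length (bits)
    m: int = MHC_BITS          # MHC PBR length (bits)
    K: int = 10                # pathogen generations per host generation
    G: int = 5000              # total host generations
    mu_A: float = 5e-5         # pathogen per-site flip probability
    mu_MHC: float = 1e-4       # host per-molecule mutation probability
    mu_del: float = 1e-3       # per-gene deletion probability
    mu_dupl: float = 1e-3      # per-gene duplication probability
    alpha: float = 0.02        # cost factor on repertoire size
    host_mutation_mode: str = "micro"   # "micro" | "macro"
    seed: int = 0
    summary_fraction: float = 0.25      # final fraction of generations averaged

    def __post_init__(self) -> None:
        for name in ("N_H", "N_P", "S", "a", "m", "K", "G"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer; got {v!r}")
        for name in ("mu_A", "mu_MHC", "mu_del", "mu_dupl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v!r}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0; got {self.alpha!r}")
        if not 0.0 < self.summary_fraction <= 1.0:
            raise ValueError(
                f"summary_fraction must lie in (0, 1]; got {self.summary_fraction!r}"
            )
        if self.host_mutation_mode not in ("micro", "macro"):
            raise ValueError("host_mutation_mode must be 'micro' or 'macro'")
        if not 1 <= self.m <= _MAX_M:
            raise ValueError(f"m must lie in [1, {_MAX_M}]; got {self.m}")
        if self.a < self.m:
            raise ValueError("antigen length a must be >= MHC length m")

    @classmethod
    def paper(cls, **overrides) -> "SimulationConfig":
        """The published full-scale operating point (override S, mu_A, alpha...)."""
        return cls(**overrides)

    @classmethod
    def desk(cls, **overrides) -> "SimulationConfig":
        """A desk-scale preset for interactive use: 200 hosts, 600 generations."""
        params = dict(N_H=200, N_P=200, S=8, G=600, alpha=0.02, mu_A=5e-5)
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# FASTA-like text dumps (0/1 sequences)
# ---------------------------------------------------------------------------

def _bit_line(bits: Iterable[int]) -> str:
    return "".join("1" if b else "0" for b in bits)


def dump_host_genomes(genomes: Sequence[HostGenome], handle: IO[str]) -> None:
    """Write genomes as FASTA-like text: one record per chromosome.

    The sequence of a chromosome is the concatenation of its genes' m-bit
    patterns, written as 0/1 characters.
    """
    for i, g in enumerate(genomes):
        for label, chrom in (("a", g.chrom_a), ("b", g.chrom_b)):
            handle.write(f">host_{i}|chrom_{label}|n_genes={len(chrom)}\n")
            seq = "".join(str(MHCVariant(int(p))) for p in chrom.genes)
            handle.write(seq + "\n")


def load_host_genomes(handle: IO[str], m: int = MHC_BITS) -> list[HostGenome]:
    """Read genomes written by :func:`dump_host_genomes`."""
    chroms: dict[int, dict[str, Chromosome]] = {}
    header = None
    for line in handle:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            header = line[1:]
        else:
            if header is None:
                raise ValueError("sequence line before any header")
            fields = header.split("|")
            host_id = int(fields[0].split("_")[1])
            label = fields[1].split("_")[1]
            if len(line) % m:
                raise ValueError("chromosome sequence length not a multiple of m")
            genes = [bits_to_pattern([int(c) for c in line[k : k + m]])
                     for k in range(0, len(line), m)]
            chroms.setdefault(host_id, {})[label] = Chromosome(genes)
    return [
        HostGenome(chroms[i]["a"], chroms[i]["b"]) for i in sorted(chroms)
    ]


def dump_antigens(
    antigens_by_species: Sequence[Sequence[Antigen]], handle: IO[str]
) -> None:
    """Write antigens as FASTA-like text with species and individual ids."""
    for s, antigens in enumerate(antigens_by_species):
        for i, ag in enumerate(antigens):
            handle.write(f">species_{s}|individual_{i}\n")
            handle.write(_bit_line(ag.bits) + "\n")
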