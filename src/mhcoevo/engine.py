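"""The Red Queen scheduler: infection rounds, host fitness and reproduction.

One host generation consists of K pathogen generations.  In each pathogen
generation every host meets one randomly drawn free-living individual of
every pathogen species that has not yet infected it; an encounter the host
cannot present establishes an infection, and the successful clone becomes
resident in that host for the remainder of the host generation, ecologically
excluding other clones of its species.  Pathogens then reproduce clonally in
proportion to the hosts they infect (residents are credited their occupied
host in every subsequent round), with per-site antigen mutation.  After the
K rounds, host fitness is

    f_host = P * exp(-(alpha * N)^2)

with P the number of species the host presented at every attempt (thereby
avoiding infection), N its number of unique MHC variants and alpha the cost
factor penalizing large repertoires.  Hosts are outcrossing hermaphrodites:
each of the N_H offspring draws two fitness-proportional parents (repeats
and selfing allowed), receives one uniformly chosen chromosome from each,
and each transmitted chromosome undergoes copy-number mutation followed by
micro- or macromutation.

Event order within a host generation, fixed for reproducibility:
K x (infection round -> pathogen reproduction) -> host fitness -> stats ->
host reproduction -> state reset.  A single seeded RNG stream drives every
stochastic draw in a fixed call order, so identical seed and configuration
give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import pathlib

import numpy as np
import pandas as pd

from . import _kernels
from .genome_types import (
    Antigen,
    Chromosome,
    HostGenome,
    SimulationConfig,
)
from .mutation import (
    copy_number_mutate,
    macromutate,
    micromutate,
    per_bit_rate,
    sample_distinct_sites,
)
from .stats import (
    GenerationStats,
    RunSummary,
    stats_frame,
    summarize_run,
)

logger = logging.getLogger(__name__)


def host_fitness(P: int, N: int, alpha: float) -> float:
    """Host fitness P * exp(-(alpha*N)^2)."""
    if P < 0 or N < 1 or alpha < 0:
        raise ValueError("require P >= 0, N >= 1, alpha >= 0")
    return P * math.exp(-((alpha * N) ** 2))


def proportional_choice(
    rng: np.random.Generator, weights: np.ndarray, size: int
) -> np.ndarray:
    """Draw ``size`` indices with probability proportional to ``weights``.

    Falls back to uniform sampling when all weights are zero (the degenerate
    edge where no individual earned any fitness).
    """
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0.0:
        return rng.integers(0, weights.size, size=size)
    return rng.choice(weights.size, size=size, p=weights / total)


class Host:
    """One diploid host with its per-generation infection/fitness state."""

    __slots__ = ("genome", "variants", "_only", "fitness", "n_presented")

    def __init__(self, genome: HostGenome):
        self.genome = genome
        #: cached sorted unique patterns; genomes are fixed within a generation
        self.variants = genome.variant_array()
        # scalar fast path for the common single-variant repertoire
        self._only = int(self.variants[0]) if self.variants.size == 1 else -1
        self.fitness = 0.0
        self.n_presented = 0

    @property
    def n_unique(self) -> int:
        return int(self.variants.size)


class PathogenSpecies:
    """A clonal pathogen species: free-living pool plus within-host residents."""

    __slots__ = ("index", "antigens", "credits", "residents", "resident_credits")

    def __init__(self, index: int, antigens: list[Antigen]):
        self.index = index
        self.antigens = antigens                       # free pool, size N_P
        self.credits = np.zeros(len(antigens), dtype=np.int64)
        self.residents: dict[int, Antigen] = {}        # host id -> clone
        self.resident_credits: dict[int, int] = {}

    @property
    def n_individuals(self) -> int:
        return len(self.antigens)

    def clear_generation_state(self) -> None:
        self.residents.clear()
        self.resident_credits.clear()
        self.credits[:] = 0


@dataclasses.dataclass
class WorldState:
    """Complete simulation state at one point in time."""

    config: SimulationConfig
    hosts: list[Host]
    species: list[PathogenSpecies]
    infected: np.ndarray          # (N_H, S) bool: species s infected host h
    generation: int
    rng: np.random.Generator


def initialize_world(config: SimulationConfig) -> WorldState:
    """Seeded initial state.

    Host genomes start minimal: one uniformly random gene per chromosome
    (N of 1 or 2), letting copy number evolve from the floor.  Each pathogen
    species is initiated as a single random antigen cloned N_P times, so
    individuals share an evolutionary origin within species while species
    are independent.
    """
    rng = np.random.default_rng(config.seed)
    start_genes = rng.integers(0, 1 << config.m, size=(config.N_H, 2), dtype=np.uint32)
    hosts = [
        Host(HostGenome(Chromosome(start_genes[i, :1]), Chromosome(start_genes[i, 1:])))
        for i in range(config.N_H)
    ]
    species = []
    for s in range(config.S):
        founder = Antigen.random(rng, length=config.a, m=config.m)
        species.append(PathogenSpecies(s, [founder] * config.N_P))
    infected = np.zeros((config.N_H, config.S), dtype=bool)
    return WorldState(
        config=config,
        hosts=hosts,
        species=species,
        infected=infected,
        generation=0,
        rng=rng,
    )


def pathogen_round(world: WorldState) -> WorldState:
    """One infection round: every uninfected (host, species) pair gets one
    encounter with a uniformly drawn free-living individual.

    Residents established in earlier rounds are credited their occupied host;
    a failed presentation infects the host, makes the drawn clone resident
    and credits the free-living individual.  A host already infected by a
    species is skipped for that species for the rest of the host generation.
    """
    rng = world.rng
    infected = world.infected
    hosts = world.hosts
    for sp in world.species:
        for h in sp.resident_credits:
            sp.resident_credits[h] += 1
        free_hosts = np.flatnonzero(~infected[:, sp.index])
        if free_hosts.size == 0:
            continue
        draws = rng.integers(0, sp.n_individuals, size=free_hosts.size)
        antigens = sp.antigens
        for h, j in zip(free_hosts.tolist(), draws.tolist()):
            ag = antigens[j]
            host = hosts[h]
            if host._only >= 0:
                hit = ag.presence[host._only]
            else:
                hit = _kernels.any_present(ag.presence, host.variants)
            if not hit:
                infected[h, sp.index] = True
                sp.residents[h] = ag
                sp.resident_credits[h] = 0
                sp.credits[j] += 1
    return world


def pathogen_reproduce(
    species: PathogenSpecies, mu_A: float, rng: np.random.Generator
) -> PathogenSpecies:
    """Clonal reproduction proportional to infection credits, then mutation.

    The selection pool is the free-living population plus the resident
    clones; N_P offspring replace the free pool (uniform fallback when every
    credit is zero).  Residents stay sequestered in their hosts but mutate
    each pathogen generation (within-host evolution).  Credits reset.
    """
    n_p = species.n_individuals
    resident_items = list(species.residents.items())
    pool = species.antigens + [ag for _, ag in resident_items]
    weights = np.concatenate(
        [
            species.credits.astype(float),
            np.array(
                [float(species.resident_credits[h]) for h, _ in resident_items]
            ),
        ]
    )
    if weights.sum() <= 0.0:
        logger.debug(
            "species %d: all infection credits zero; uniform resampling",
            species.index,
        )
    parent_idx = proportional_choice(rng, weights, n_p)
    length = pool[0].length
    n_flips = rng.binomial(length, mu_A, size=n_p) if mu_A > 0 else np.zeros(n_p, int)
    offspring = []
    for i in range(n_p):
        ag = pool[parent_idx[i]]
        k = int(n_flips[i])
        if k:
            ag = ag.with_flips(sample_distinct_sites(rng, length, k))
        offspring.append(ag)
    species.antigens = offspring
    species.credits = np.zeros(n_p, dtype=np.int64)
    # within-host evolution of resident clones
    if resident_items and mu_A > 0:
        res_flips = rng.binomial(length, mu_A, size=len(resident_items))
        for (h, ag), k in zip(resident_items, res_flips):
            if k:
                species.residents[h] = ag.with_flips(
                    sample_distinct_sites(rng, length, int(k))
                )
    for h in species.resident_credits:
        species.resident_credits[h] = 0
    return species


def _compute_fitness(world: WorldState) -> np.ndarray:
    cfg = world.config
    n_infections = world.infected.sum(axis=1)
    fitness = np.empty(cfg.N_H)
    for h, host in enumerate(world.hosts):
        P = cfg.S - int(n_infections[h])
        host.n_presented = P
        host.fitness = host_fitness(P, host.n_unique, cfg.alpha)
        fitness[h] = host.fitness
    return fitness


def _generation_stats(world: WorldState, fitness: np.ndarray) -> GenerationStats:
    inv = np.array([h.n_unique for h in world.hosts], dtype=np.int64)
    pnv = int(
        np.unique(np.concatenate([h.variants for h in world.hosts])).size
    )
    mean_fit = float(fitness.mean())
    sd_fit = float(fitness.std(ddof=0))
    cv = sd_fit / mean_fit if mean_fit > 0 else math.nan
    loci = float(np.mean([h.genome.n_loci for h in world.hosts]))
    return GenerationStats(
        generation=world.generation,
        mean_inv=float(inv.mean()),
        sd_inv=float(inv.std(ddof=0)),
        pnv=pnv,
        mean_fitness=mean_fit,
        sd_fitness=sd_fit,
        cv_fitness=cv,
        mean_loci_per_genome=loci,
    )


def _reproduce_hosts(
    world: WorldState, fitness: np.ndarray, mu_bit: float
) -> list[Host]:
    cfg = world.config
    rng = world.rng
    if fitness.sum() <= 0.0:
        logger.warning(
            "generation %d: total host fitness is zero; uniform parent sampling",
            world.generation,
        )
    parents = proportional_choice(rng, fitness, size=2 * cfg.N_H).reshape(cfg.N_H, 2)
    which_chrom = rng.integers(0, 2, size=(cfg.N_H, 2))
    old_hosts = world.hosts
    new_hosts = []
    macro = cfg.host_mutation_mode == "macro"
    for i in range(cfg.N_H):
        chroms = []
        for parent, c in zip(parents[i], which_chrom[i]):
            g = old_hosts[parent].genome
            ch = g.chrom_a if c == 0 else g.chrom_b
            ch = copy_number_mutate(ch, cfg.mu_dupl, cfg.mu_del, rng)
            if macro:
                ch = macromutate(ch, cfg.mu_MHC, rng, m=cfg.m)
            else:
                ch = micromutate(ch, mu_bit, rng, m=cfg.m)
            chroms.append(ch)
        new_hosts.append(Host(HostGenome(chroms[0], chroms[1])))
    return new_hosts


def host_generation(
    world: WorldState, config: SimulationConfig | None = None
) -> GenerationStats:
    """Advance the world by one full host generation; return its stats.

    The returned statistics describe the population that just interacted
    with pathogens (i.e. before reproduction replaced it).
    """
    cfg = config if config is not None else world.config
    for _ in range(cfg.K):
        pathogen_round(world)
        for sp in world.species:
            pathogen_reproduce(sp, cfg.mu_A, world.rng)
    fitness = _compute_fitness(world)
    stats = _generation_stats(world, fitness)
    mu_bit = per_bit_rate(cfg.mu_MHC, cfg.m)
    world.hosts = _reproduce_hosts(world, fitness, mu_bit)
    world.infected[:] = False
    for sp in world.species:
        sp.clear_generation_state()
    world.generation += 1
    return stats


def take_snapshot(world: WorldState) -> dict:
    """Detailed record of the interacting population.

    Call after fitness assignment and before reproduction: per host the gene
    patterns of both chromosomes, N, the number of presented species and
    fitness; per species a summary of antigenic diversity.
    """
    hosts = [
        {
            "id": h,
            "chrom_a": host.genome.chrom_a.genes.tolist(),
            "chrom_b": host.genome.chrom_b.genes.tolist(),
            "n_unique": host.n_unique,
            "n_presented": host.n_presented,
            "fitness": host.fitness,
        }
        for h, host in enumerate(world.hosts)
    ]
    species = []
    for sp in world.species:
        seen: dict[int, int] = {}
        distinct = []
        for ag in sp.antigens:
            key = id(ag)
            if key not in seen:
                seen[key] = len(distinct)
                distinct.append(ag)
        species.append(
            {
                "index": sp.index,
                "n_individuals": sp.n_individuals,
                "n_distinct_antigens": len(distinct),
                "n_resident_clones": len(sp.residents),
            }
        )
    return {"generation": world.generation, "hosts": hosts, "species": species}


@dataclasses.dataclass
class RunOutputs:
    """Everything a run produces: config echo, per-generation stats,
    final-generation snapshot and the window-averaged summary."""

    config: SimulationConfig
    stats: pd.DataFrame
    snapshot: dict
    summary: RunSummary

    def write(self, outdir: str | pathlib.Path) -> pathlib.Path:
        """Write stats.csv, snapshot.json, config.json and summary.json."""
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.stats.to_csv(outdir / "stats.csv", index=False)
        (outdir / "snapshot.json").write_text(
            json.dumps(self.snapshot, sort_keys=True)
        )
        (outdir / "config.json").write_text(self.config.to_json())
        (outdir / "summary.json").write_text(
            json.dumps(self.summary.to_dict(), sort_keys=True, indent=2)
        )
        return outdir


def run_simulation(config: SimulationConfig) -> RunOutputs:
    """Run G host generations from a seeded initial state.

    The final-generation snapshot is taken after fitness assignment of
    generation G (the last interacting population), before the reproduction
    step that would replace it.
    """
    world = initialize_world(config)
    records: list[GenerationStats] = []
    snapshot: dict = {}
    for g in range(config.G):
        last = g == config.G - 1
        if not last:
            records.append(host_generation(world))
            continue
        # final generation: interact, record, snapshot; skip the reproduction
        for _ in range(config.K):
            pathogen_round(world)
            for sp in world.species:
                pathogen_reproduce(sp, config.mu_A, world.rng)
        fitness = _compute_fitness(world)
        records.append(_generation_stats(world, fitness))
        snapshot = take_snapshot(world)
    frame = stats_frame(records)
    summary = summarize_run(
        frame, snapshot, config.summary_fraction, config=config.to_dict()
    )
    return RunOutputs(config=config, stats=frame, snapshot=snapshot, summary=summary)
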