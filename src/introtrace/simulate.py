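"""Forward-time simulator of microsatellite data under a scripted
importation history.

The generator emulates serial biological-control introductions: a
Wright-Fisher native population with stepwise mutation, founder events with
documented propagule sizes (release bottlenecks), admixture when a
destination receives material from several sources, drift between events,
and a genotyping noise layer (missing calls and null alleles).  A truth
record accompanies every replayed dataset so downstream inference can be
scored against the scripted history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data import MISSING, GenotypeDataset
from .history import ImportationHistory

__all__ = [
    "SimulationConfig",
    "Population",
    "simulate_base_population",
    "apply_founder_event",
    "admix_populations",
    "evolve",
    "sample_dataset",
    "replay_importation_history",
    "degrade_genotypes",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the forward simulation.

    ``mutation_rate`` is the per-copy per-generation probability of a
    stepwise mutation (+-1 repeat unit, symmetric).  ``effective_size`` is
    the per-population diploid size populations recover to one generation
    after founding.  ``generations_per_year`` converts ledger years to
    Wright-Fisher generations (two per year approximates weevil
    voltinism).  ``missing_rate`` and ``null_allele_freq`` parameterise the
    genotyping noise applied to sampled datasets.
    """

    n_loci: int = 8
    alleles_per_locus_init: int = 6
    effective_size: int = 200
    generations_per_year: float = 2.0
    mutation_rate: float = 5e-4
    missing_rate: float = 0.0
    null_allele_freq: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effective_size < 2:
            raise ValueError("effective_size must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.alleles_per_locus_init < 1:
            raise ValueError("alleles_per_locus_init must be >= 1")
        for name in ("mutation_rate", "missing_rate", "null_allele_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Population:
    """Internal population state: diploid genotypes (n, n_loci, 2).

    Allele codes are integer fragment sizes; stepwise mutation moves a
    code by one motif unit.
    """

    genotypes: np.ndarray

    @property
    def size(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def allele_counts(self, locus: int) -> dict[int, int]:
        alleles, counts = np.unique(self.genotypes[:, locus, :], return_counts=True)
        return {int(a): int(c) for a, c in zip(alleles, counts)}

    def copy(self) -> "Population":
        return Population(self.genotypes.copy())


#: Allele codes start at this fragment size; initial alleles are spaced one
#: motif unit apart so the stepwise model stays on the same ladder.
_BASE_ALLELE = 120


def simulate_base_population(
    cfg: SimulationConfig, burn_in_generations: int = 200
) -> Population:
    """Create and burn in the native-range population.

    Individuals start with alleles drawn uniformly from
    ``alleles_per_locus_init`` codes, then undergo ``burn_in_generations``
    of Wright-Fisher multinomial resampling with stepwise mutation.
    """
    if burn_in_generations < 0:
        raise ValueError("burn_in_generations must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    init = rng.integers(
        _BASE_ALLELE,
        _BASE_ALLELE + cfg.alleles_per_locus_init,
        size=(cfg.effective_size, cfg.n_loci, 2),
    )
    pop = Population(init.astype(np.int64))
    return evolve(pop, cfg, burn_in_generations, rng)


def evolve(
    pop: Population,
    cfg: SimulationConfig,
    generations: int,
    rng: np.random.Generator,
) -> Population:
    """Run ``generations`` of Wright-Fisher reproduction with mutation.

    Each offspring draws a mother and a father uniformly (with
    replacement) and inherits one random allele from each; the population
    recovers to ``cfg.effective_size`` immediately (instant post-bottleneck
    growth).
    """
    g = pop.genotypes
    N = cfg.effective_size
    L = g.shape[1]
    cols = np.arange(L)[None, :]
    for _ in range(generations):
        n_par = g.shape[0]
        mothers = rng.integers(n_par, size=N)[:, None]
        fathers = rng.integers(n_par, size=N)[:, None]
        from_mother = g[mothers, cols, rng.integers(2, size=(N, L))]
        from_father = g[fathers, cols, rng.integers(2, size=(N, L))]
        g = np.stack([from_mother, from_father], axis=2)
        if cfg.mutation_rate > 0:
            hits = rng.random(g.shape) < cfg.mutation_rate
            if hits.any():
                steps = rng.choice((-1, 1), size=int(hits.sum()))
                g = g.copy()
                g[hits] += steps
                np.maximum(g, 1, out=g)  # fragment sizes stay positive
    return Population(g)


def apply_founder_event(
    pop: Population, propagule_size: int, seed: int | np.random.Generator
) -> Population:
    """Found a new population from ``propagule_size`` individuals sampled
    without replacement (the release bottleneck)."""
    if propagule_size < 1:
        raise ValueError("propagule_size must be >= 1")
    if propagule_size > pop.size:
        raise ValueError(
            f"propagule_size {propagule_size} exceeds population size {pop.size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(pop.size, size=propagule_size, replace=False)
    return Population(pop.genotypes[chosen].copy())


def admix_populations(
    pop_a: Population,
    pop_b: Population,
    proportion_a: float,
    total_founders: int,
    seed: int | np.random.Generator,
) -> Population:
    """Found a population from two sources: ``round(proportion_a * total)``
    founders from A, the remainder from B."""
    if not 0.0 <= proportion_a <= 1.0:
        raise ValueError("proportion_a must lie in [0, 1]")
    if total_founders < 2:
        raise ValueError("total_founders must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_a = int(round(proportion_a * total_founders))
    n_b = total_founders - n_a
    parts = []
    for pop, n in ((pop_a, n_a), (pop_b, n_b)):
        if n == 0:
            continue
        if n > pop.size:
            raise ValueError(f"founder draw {n} exceeds source size {pop.size}")
        chosen = rng.choice(pop.size, size=n, replace=False)
        parts.append(pop.genotypes[chosen])
    return Population(np.concatenate(parts, axis=0).copy())


def sample_dataset(
    populations: Mapping[str, Population],
    n_per_pop: int | Mapping[str, int],
    seed: int | np.random.Generator,
    locus_prefix: str = "L",
) -> GenotypeDataset:
    """Draw individuals (without replacement) from each population into a
    :class:`GenotypeDataset`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    individuals, pops, blocks = [], [], []
    for label, pop in populations.items():
        n = n_per_pop if isinstance(n_per_pop, int) else n_per_pop.get(label, 25)
        n = min(n, pop.size)
        chosen = rng.choice(pop.size, size=n, replace=False)
        blocks.append(pop.genotypes[chosen])
        individuals += [f"{label}_{i:03d}" for i in range(n)]
        pops += [label] * n
    n_loci = blocks[0].shape[1]
    loci = [f"{locus_prefix}{j + 1}" for j in range(n_loci)]
    return GenotypeDataset(individuals, pops, loci, np.concatenate(blocks, axis=0))


@dataclass
class TruthRecord:
    """Scripted ground truth for a replayed history."""

    step_counts: dict[str, int]
    founding: list[dict] = field(default_factory=list)
    seed: int = 0


def replay_importation_history(
    history: ImportationHistory,
    cfg: SimulationConfig,
    growth_generations_per_step: int = 10,
    burn_in_generations: int = 200,
    n_sample_per_pop: int | Mapping[str, int] = 25,
) -> tuple[GenotypeDataset, TruthRecord]:
    """Simulate the scripted introduction history and sample a dataset.

    The native population is burned in, events execute in year order
    (same-year events into one destination merge into a single admixture
    with proportions proportional to propagule sizes; a later event into an
    existing population admixes into the standing stock with proportion
    ``propagule / (propagule + N_current)``), every population drifts
    between event years at ``cfg.generations_per_year``, and
    ``growth_generations_per_step`` generations of growth follow the final
    event before sampling.  Propagule sizes larger than the source
    population are capped at the source size.

    Returns the sampled dataset (with ``cfg`` noise applied) and a truth
    record holding per-population introduction-step counts and the
    founding log.
    """
    history.validate()
    rng = np.random.default_rng(cfg.seed)
    native = history.native_label
    states: dict[str, Population] = {
        native: simulate_base_population(cfg, burn_in_generations)
    }
    truth = TruthRecord(step_counts=history.step_counts(), seed=cfg.seed)

    years = sorted({e.year for e in history.events})
    current_year = years[0] if years else 0
    for year in years:
        gens = int(round((year - current_year) * cfg.generations_per_year))
        if gens > 0:
            for label in states:
                states[label] = evolve(states[label], cfg, gens, rng)
        current_year = year
        todays = [e for e in history.events if e.year == year]
        by_dest: dict[str, list] = {}
        for e in todays:
            by_dest.setdefault(e.destination, []).append(e)
        for dest, evts in by_dest.items():
            for e in evts:
                if e.source not in states:
                    raise ValueError(
                        f"event {e.source}->{e.destination} ({e.year}): "
                        "source population does not exist yet"
                    )
            sources = [states[e.source] for e in evts]
            sizes = [min(e.propagule_size, states[e.source].size) for e in evts]
            if dest not in states:
                if len(evts) == 1:
                    newpop = apply_founder_event(sources[0], sizes[0], rng)
                else:
                    # merge same-year shipments: founders proportional to
                    # propagule sizes
                    pooled = []
                    for src, n in zip(sources, sizes):
                        chosen = rng.choice(src.size, size=n, replace=False)
                        pooled.append(src.genotypes[chosen])
                    newpop = Population(np.concatenate(pooled, axis=0))
                states[dest] = newpop
            else:
                for src, n in zip(sources, sizes):
                    standing = states[dest]
                    prop_new = n / (n + standing.size)
                    states[dest] = admix_populations(
                        src, standing, prop_new, max(2, n + standing.size), rng
                    )
            truth.founding.append(
                {
                    "destination": dest,
                    "year": year,
                    "sources": [e.source for e in evts],
                    "founder_counts": sizes,
                }
            )
        # one generation of instant recovery to effective size after founding
        for dest in by_dest:
            states[dest] = evolve(states[dest], cfg, 1, rng)

    if growth_generations_per_step > 0:
        for label in states:
            states[label] = evolve(states[label], cfg, growth_generations_per_step, rng)

    ds = sample_dataset(states, n_sample_per_pop, rng)
    if cfg.missing_rate > 0 or cfg.null_allele_freq > 0:
        ds = degrade_genotypes(
            ds, cfg.missing_rate, cfg.null_allele_freq,
            int(rng.integers(2**31)),
        )
    return ds, truth


def degrade_genotypes(
    ds: GenotypeDataset,
    missing_rate: float,
    null_allele_freq: float,
    seed: int,
) -> GenotypeDataset:
    """Apply genotyping noise: random dropout and segregating null alleles.

    With ``null_allele_freq`` q, each allele copy is independently a null
    (non-amplifying) variant with probability q: a null/X genotype scores
    as homozygous X, and null/null scores as missing.  With
    ``missing_rate`` m, whole genotypes additionally drop to missing.
    """
    for name, v in (("missing_rate", missing_rate), ("null_allele_freq", null_allele_freq)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if missing_rate == 0 and null_allele_freq == 0:
        return ds
    rng = np.random.default_rng(seed)
    calls = ds.calls.copy()
    typed = calls[:, :, 0] != MISSING
    if null_allele_freq > 0:
        null_hits = (rng.random(calls.shape) < null_allele_freq) & typed[:, :, None]
        one_null = null_hits.sum(axis=2) == 1
        both_null = null_hits.all(axis=2)
        # null/X appears homozygous for the amplifying allele X
        surviving = np.where(null_hits[:, :, 0], calls[:, :, 1], calls[:, :, 0])
        for slot in (0, 1):
            calls[:, :, slot] = np.where(one_null, surviving, calls[:, :, slot])
        calls[both_null] = MISSING
    if missing_rate > 0:
        drop = rng.random(typed.shape) < missing_rate
        calls[drop] = MISSING
    return GenotypeDataset(ds.individuals, ds.populations, ds.loci, calls)
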