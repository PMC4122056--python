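"""Elitist genetic algorithm over sub-diagonal genotypes.

Each generation keeps the best ``ceil((1 - crossover_rate) * h)``
individuals unchanged (elitism, which makes the best fitness monotone
non-increasing), refills the rest by single-point crossover of
consecutive fitness-ranked parents, then mutates ``ceil(mutation_rate
* h)`` randomly chosen non-elite individuals by swapping one active
bit for an inactive one (with retries when the newly activated helix
is fully conflicted away).  The run stops when the best fitness has
not changed for ``patience`` generations, or at ``max_generations``.

A single seeded RNG stream drives initialization, crossover cuts and
mutation choices in that order, so identical configuration and inputs
reproduce bit-identical results.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import dotmatrix, energy as energy_mod, sequences
from .dotmatrix import SubDiagonalSet
from .genotype import Genotype, Individual, construct_individual
from .sequences import JointSequence, RnaSequence

logger = logging.getLogger(__name__)


class NoComplementarityError(ValueError):
    """The two sequences admit no candidate helix at all."""


class StopReason(enum.Enum):
    CONVERGED = "converged"
    MAX_GENERATIONS = "max_generations"


@dataclass(frozen=True)
class GaConfig:
    """Tunable parameters of the search.

    Defaults: population h = 40, at most 20 generations, crossover
    rate 0.9, mutation rate 0.1, and an initialization cap of
    max(n, m) active helices per individual.
    """

    population_size: int = 40
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    max_generations: int = 20
    patience: int = 5
    active_cap: int | None = None  # None -> max(n, m)
    gu_threshold: float = 0.14
    min_pairs: int = 2
    min_hairpin_loop: int = 3
    seed: int = 0
    energy_model: str = "builtin"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class Population:
    individuals: list[Individual]
    generation: int = 0

    def sort(self) -> None:
        self.individuals.sort(key=lambda ind: ind.fitness)

    @property
    def best(self) -> Individual:
        return self.individuals[0]

    def mean_fitness(self) -> float:
        return sum(i.fitness for i in self.individuals) / len(self.individuals)

    def distinct_genotypes(self) -> int:
        return len({i.genotype.bits for i in self.individuals})


@dataclass(frozen=True)
class GenerationStats:
    generation: int
    best_fitness: float
    mean_fitness: float
    distinct_genotypes: int


@dataclass
class GaResult:
    best: Individual
    history: list[GenerationStats]
    generations_run: int
    stop_reason: StopReason
    js: JointSequence
    diagonals: SubDiagonalSet


def random_genotype(
    rng: np.random.Generator, num_diagonals: int, active_cap: int
) -> Genotype:
    """Uniformly many (in [1, min(|D^R|, cap)]) helices, chosen uniformly."""
    cap = max(1, min(num_diagonals, active_cap))
    k = int(rng.integers(1, cap + 1))
    chosen = rng.choice(num_diagonals, size=k, replace=False)
    bits = [0] * num_diagonals
    for idx in chosen:
        bits[int(idx)] = 1
    return Genotype(bits=tuple(bits), active_cap=active_cap)


def _build(
    bits: Genotype,
    diagonals: SubDiagonalSet,
    js: JointSequence,
    model: energy_mod.EnergyModel,
) -> Individual:
    ind = construct_individual(bits, diagonals, js)
    energy_mod.fitness(model, ind, js)
    return ind


def init_population(
    config: GaConfig,
    diagonals: SubDiagonalSet,
    js: JointSequence,
    rng: np.random.Generator,
    model: energy_mod.EnergyModel,
) -> Population:
    if len(diagonals) == 0:
        raise NoComplementarityError(
            "no complementarity found between or within the two sequences"
        )
    cap = config.active_cap or max(js.n, js.m)
    individuals = [
        _build(random_genotype(rng, len(diagonals), cap), diagonals, js, model)
        for _ in range(config.population_size)
    ]
    pop = Population(individuals=individuals, generation=0)
    pop.sort()
    return pop


def crossover_pair(
    parent1: Genotype,
    parent2: Genotype,
    k: int,
    diagonals: SubDiagonalSet,
    js: JointSequence,
    model: energy_mod.EnergyModel,
) -> tuple[Individual, Individual]:
    """Single-point crossover at cut position k (1-based, inclusive prefix)."""
    if not 1 <= k <= len(parent1):
        raise ValueError(f"cut position {k} outside [1, {len(parent1)}]")
    b1, b2 = parent1.bits, parent2.bits
    child1 = Genotype(b1[:k] + b2[k:], parent1.active_cap)
    child2 = Genotype(b2[:k] + b1[k:], parent2.active_cap)
    return (
        _build(child1, diagonals, js, model),
        _build(child2, diagonals, js, model),
    )


def mutate(
    individual: Individual,
    config: GaConfig,
    rng: np.random.Generator,
    diagonals: SubDiagonalSet,
    js: JointSequence,
    model: energy_mod.EnergyModel,
) -> Individual:
    """Swap one active bit for an inactive one, retrying dead activations.

    If activating a helix contributes nothing (its pairs are fully
    conflicted away), another inactive bit is tried, up to |D^R|
    attempts.  Degenerate genotypes (no 1-bit or no 0-bit) are returned
    unchanged.
    """
    bits = list(individual.genotype.bits)
    ones = [i for i, b in enumerate(bits) if b == 1]
    zeros = [i for i, b in enumerate(bits) if b == 0]
    if not ones or not zeros:
        return individual
    off = int(ones[int(rng.integers(0, len(ones)))])
    bits[off] = 0
    # The cleared bit is not re-eligible; try inactive bits in random
    # order until the activated helix actually contributes pairs.
    order = rng.permutation(len(zeros))
    max_tries = min(len(zeros), len(diagonals))
    fallback: Individual | None = None
    for idx in order[:max_tries]:
        on = zeros[int(idx)]
        bits[on] = 1
        child = _build(
            Genotype(tuple(bits), individual.genotype.active_cap),
            diagonals,
            js,
            model,
        )
        if on in child.component_indices:
            return child
        fallback = child
        bits[on] = 0
    return fallback if fallback is not None else individual


def next_generation(
    pop: Population,
    config: GaConfig,
    rng: np.random.Generator,
    diagonals: SubDiagonalSet,
    js: JointSequence,
    model: energy_mod.EnergyModel,
) -> Population:
    h = config.population_size
    num_elite = min(h, math.ceil((1.0 - config.crossover_rate) * h))
    new: list[Individual] = list(pop.individuals[:num_elite])

    # Cross consecutive fitness-ranked parents (1st with 2nd, ...),
    # cycling through the ranking until the population is refilled.
    pair_idx = 0
    num_pairs = h // 2
    while len(new) < h:
        i = (2 * pair_idx) % (2 * num_pairs)
        p1 = pop.individuals[i]
        p2 = pop.individuals[i + 1]
        k = int(rng.integers(1, len(diagonals) + 1))
        c1, c2 = crossover_pair(
            p1.genotype, p2.genotype, k, diagonals, js, model
        )
        new.append(c1)
        if len(new) < h:
            new.append(c2)
        pair_idx += 1

    num_mut = min(h - num_elite, math.ceil(config.mutation_rate * h))
    if num_mut > 0 and h > num_elite:
        targets = rng.choice(
            np.arange(num_elite, h), size=num_mut, replace=False
        )
        for t in targets:
            new[int(t)] = mutate(new[int(t)], config, rng, diagonals, js, model)

    out = Population(individuals=new, generation=pop.generation + 1)
    out.sort()
    return out


def prepare_search_space(
    first: RnaSequence, second: RnaSequence, config: GaConfig
) -> tuple[JointSequence, SubDiagonalSet]:
    """Concatenate, build the dot matrix, enumerate and G-U-filter D^R."""
    js = sequences.concatenate(first, second)
    matrix = dotmatrix.build_matrix(js)
    diags = dotmatrix.extract_subdiagonals(
        matrix, js, config.min_pairs, config.min_hairpin_loop
    )
    return js, dotmatrix.filter_gu(diags, config.gu_threshold, config.min_pairs)


def run(
    config: GaConfig, first: RnaSequence, second: RnaSequence
) -> GaResult:
    """Full pipeline: search-space construction, then the evolutionary loop."""
    model = energy_mod.get_model(config.energy_model)
    js, diags = prepare_search_space(first, second, config)
    if len(diags) == 0:
        raise NoComplementarityError(
            "no complementarity found between or within the two sequences"
        )
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, diags, js, rng, model)

    history: list[GenerationStats] = []

    def record(p: Population) -> None:
        stats = GenerationStats(
            generation=p.generation,
            best_fitness=p.best.fitness,
            mean_fitness=p.mean_fitness(),
            distinct_genotypes=p.distinct_genotypes(),
        )
        history.append(stats)
        logger.info(
            "generation=%d best=%.2f mean=%.2f distinct=%d",
            stats.generation,
            stats.best_fitness,
            stats.mean_fitness,
            stats.distinct_genotypes,
        )

    record(pop)
    stagnant = 0
    stop_reason = StopReason.MAX_GENERATIONS
    while pop.generation < config.max_generations:
        prev_best = pop.best.fitness
        pop = next_generation(pop, config, rng, diags, js, model)
        record(pop)
        if pop.best.fitness == prev_best:
            stagnant += 1
        else:
            stagnant = 0
        if stagnant >= config.patience:
            stop_reason = StopReason.CONVERGED
            break

    return GaResult(
        best=pop.best,
        history=history,
        generations_run=pop.generation,
        stop_reason=stop_reason,
        js=js,
        diagonals=diags,
    )
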