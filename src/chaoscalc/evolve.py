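"""Directed evolution of peptide sequences with a pluggable fitness.

A genetic algorithm over fixed-length sequences of the 20 canonical amino
acids: the best-scoring individuals are kept (elitism) and recombined by
single-point crossover, and offspring pick up infrequent point mutations.
Fitness is *minimized* — the intended fitness is a sensing free energy,
where more negative means a better packing-defect sensor.  Simulation-backed
fitness functions plug in as plain callables; a fast built-in surrogate
rewards aromatic bulk (W, F) and hydrophobicity, the sequence signature
that strong sensors converge to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "Individual",
    "EvolutionParams",
    "GenerationStats",
    "EvolutionHistory",
    "surrogate_fitness",
    "initialize_population",
    "evaluate_fitness",
    "next_generation",
    "run_evolution",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy, used by the surrogate fitness.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

#: Extra per-residue reward for the bulky aromatics that drive membrane
#: insertion depth and tension generation; sized so tryptophan is the
#: strict per-residue optimum of the surrogate.
AROMATIC_BONUS = {"W": 8.0, "F": 4.0}

_RESIDUE_SCORE = {
    aa: KYTE_DOOLITTLE[aa] + AROMATIC_BONUS.get(aa, 0.0) for aa in AMINO_ACIDS
}


def surrogate_fitness(sequence: str) -> float:
    """Toy stand-in for an MD-derived sensing free energy (lower = better).

    The negative sum of per-residue scores (hydropathy plus aromatic
    bonuses), so the global minimum is poly-tryptophan.  Useful for
    exercising and testing the optimizer; it makes no claim of matching
    simulation-derived fitness values.
    """
    return -sum(_RESIDUE_SCORE[aa] for aa in sequence)


@dataclass
class Individual:
    """One candidate sequence with an optional cached fitness."""

    sequence: str
    fitness: float | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
        if not self.sequence:
            raise ValueError("empty sequence")


@dataclass(frozen=True)
class EvolutionParams:
    """Genetic-algorithm settings.

    Defaults: population 32, 8 parents, crossover probability 0.9,
    per-residue mutation rate 0.02, 2 elites, 24-residue sequences; the
    convergence flag trips when the best fitness has not improved for
    ``stall_window`` consecutive generations.
    """

    population_size: int = 32
    n_generations: int = 25
    n_parents: int = 8
    crossover_rate: float = 0.9
    mutation_rate: float = 0.02
    elitism_count: int = 2
    sequence_length: int = 24
    stall_window: int = 5
    seed: int = 0
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if not 0 <= self.crossover_rate <= 1 or not 0 <= self.mutation_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.n_parents > self.population_size or self.n_parents < 1:
            raise ValueError("n_parents must be in [1, population_size]")
        if self.elitism_count > self.population_size or self.elitism_count < 0:
            raise ValueError("elitism_count must be in [0, population_size]")
        if self.sequence_length < 1 or self.n_generations < 1:
            raise ValueError("sequence_length and n_generations must be positive")
        bad = set(self.alphabet) - set(AMINO_ACIDS)
        if bad or not self.alphabet:
            raise ValueError("alphabet must be a non-empty subset of the 20 amino acids")


def initialize_population(
    params: EvolutionParams, rng: np.random.Generator | None = None
) -> list[Individual]:
    """Uniform random sequences over the (possibly restricted) alphabet."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    letters = np.array(list(params.alphabet))
    picks = rng.integers(0, letters.size, size=(params.population_size, params.sequence_length))
    return [Individual("".join(letters[row])) for row in picks]


def evaluate_fitness(
    individual: Individual, fitness_fn: Callable[[str], float]
) -> float:
    """Evaluate (and cache) the fitness of one individual."""
    if individual.fitness is None:
        try:
            individual.fitness = float(fitness_fn(individual.sequence))
        except Exception as exc:
            raise RuntimeError(
                f"fitness evaluation failed for sequence {individual.sequence!r}"
            ) from exc
    return individual.fitness


def _mutate(sequence: str, rate: float, alphabet: str, rng: np.random.Generator) -> str:
    if rate == 0:
        return sequence
    seq = list(sequence)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [aa for aa in alphabet if aa != seq[i]]
        if choices:
            seq[i] = choices[rng.integers(0, len(choices))]
    return "".join(seq)


def _crossover(a: str, b: str, rng: np.random.Generator) -> str:
    point = int(rng.integers(1, len(a)))  # cut inside the sequence
    return a[:point] + b[point:]


def next_generation(
    population: Sequence[Individual],
    params: EvolutionParams,
    rng: np.random.Generator,
) -> list[Individual]:
    """Select, recombine and mutate one generation (lower fitness = better)."""
    if any(ind.fitness is None for ind in population):
        raise ValueError("all individuals must be evaluated before selection")
    ranked = sorted(population, key=lambda ind: ind.fitness)
    elites = [Individual(ind.sequence, ind.fitness) for ind in ranked[: params.elitism_count]]
    parents = ranked[: params.n_parents]
    offspring: list[Individual] = []
    while len(elites) + len(offspring) < params.population_size:
        i, j = rng.integers(0, len(parents), size=2)
        if rng.random() < params.crossover_rate and len(parents) > 1:
            child = _crossover(parents[i].sequence, parents[j].sequence, rng)
        else:
            child = parents[i].sequence
        child = _mutate(child, params.mutation_rate, params.alphabet, rng)
        offspring.append(Individual(child))
    return elites + offspring


@dataclass
class GenerationStats:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_sequence: str


@dataclass
class EvolutionHistory:
    """Audit log of one run: per-generation stats, final population, flags."""

    params: EvolutionParams
    generations: list[GenerationStats] = field(default_factory=list)
    converged: bool = False
    converged_at: int | None = None
    final_population: list[Individual] = field(default_factory=list)

    @property
    def best(self) -> GenerationStats:
        return min(self.generations, key=lambda g: g.best_fitness)

    def to_dict(self) -> dict:
        return {
            "seed": self.params.seed,
            "params": {
                "population_size": self.params.population_size,
                "n_generations": self.params.n_generations,
                "n_parents": self.params.n_parents,
                "crossover_rate": self.params.crossover_rate,
                "mutation_rate": self.params.mutation_rate,
                "elitism_count": self.params.elitism_count,
                "sequence_length": self.params.sequence_length,
                "stall_window": self.params.stall_window,
            },
            "converged": self.converged,
            "converged_at": self.converged_at,
            "generations": [
                {
                    "generation": g.generation,
                    "best_fitness": g.best_fitness,
                    "mean_fitness": g.mean_fitness,
                    "best_sequence": g.best_sequence,
                }
                for g in self.generations
            ],
        }


def run_evolution(
    params: EvolutionParams,
    fitness_fn: Callable[[str], float] = surrogate_fitness,
) -> EvolutionHistory:
    """Run the full select-recombine-mutate loop.

    With ``elitism_count`` >= 1 the best fitness is monotone non-increasing
    across generations.  The convergence flag trips at the first generation
    whose best fitness equals that of ``stall_window`` generations earlier.
    """
    rng = np.random.default_rng(params.seed)
    population = initialize_population(params, rng)
    history = EvolutionHistory(params=params)
    for gen in range(params.n_generations):
        for ind in population:
            evaluate_fitness(ind, fitness_fn)
        best = min(population, key=lambda ind: ind.fitness)
        history.generations.append(
            GenerationStats(
                generation=gen,
                best_fitness=best.fitness,
                mean_fitness=float(np.mean([ind.fitness for ind in population])),
                best_sequence=best.sequence,
            )
        )
        if (
            not history.converged
            and gen >= params.stall_window
            and history.generations[gen - params.stall_window].best_fitness
            <= best.fitness
        ):
            history.converged = True
            history.converged_at = gen
        if gen < params.n_generations - 1:
            population = next_generation(population, params, rng)
    history.final_population = population
    return history
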