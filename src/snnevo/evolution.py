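"""Evolution strategies over the 14-gene genome.

A (mu + lambda)-style loop with deterministic tournament selection, uniform
per-gene crossover (probability 0.5 per pair), per-gene Gaussian mutation
(probability 0.4, sigma expressed as a fraction of the normalized gene
range, clipped back to [0, 1]) and weak elitism: the worst offspring is
replaced by the best parent, so the population best never decreases.  The
loop stops after a fixed number of generations without improvement of the
best individual, or at a hard generation cap.

Every individual carries its own evaluation seed, derived from the master
seed and a global individual counter, so fitness is a pure function of
(genome, seed) and results do not depend on evaluation order or on the
number of parallel workers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fitness import FitnessReport
from .network import N_GENES, random_genome

__all__ = ["EAConfig", "Individual", "EAResult", "evolve_generation", "run_ea"]

Evaluator = Callable[[np.ndarray, int], FitnessReport]


@dataclass(frozen=True)
class EAConfig:
    """Settings of the evolutionary loop."""

    mu: int = 10
    lam: int = 10
    tournament_size: int = 2
    mutation_prob: float = 0.4
    mutation_sigma: float = 0.10
    crossover_prob: float = 0.5
    stop_stall: int = 100
    stop_max: int = 500
    seed: int = 0
    n_workers: int = 1

    def __post_init__(self) -> None:
        if min(self.mu, self.lam, self.tournament_size) < 1:
            raise ValueError("mu, lambda and tournament size must be >= 1")
        for p in (self.mutation_prob, self.crossover_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class Individual:
    genome: np.ndarray
    eval_seed: int
    uid: int
    fitness: FitnessReport | None = None

    @property
    def total(self) -> float:
        if self.fitness is None:
            raise RuntimeError("individual not yet evaluated")
        return self.fitness.total


@dataclass
class EAResult:
    best: Individual
    generations: int
    log: list[dict]
    stop_reason: str


def _eval_seed(master_seed: int, uid: int) -> int:
    """Independent per-individual seed below 2^31, stable in uid."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(uid)))
    return int(ss.generate_state(1)[0] % (2**31))


def _tournament(parents: list[Individual], rng: np.random.Generator, k: int) -> Individual:
    """Deterministic tournament: sample k parents, the highest total wins.

    Ties break toward the earliest sampled contestant, keeping selection
    deterministic given the sampled indices.
    """
    idx = rng.integers(0, len(parents), size=k)
    best = parents[idx[0]]
    for i in idx[1:]:
        if parents[i].total > best.total:
            best = parents[i]
    return best


def _mutate(genome: np.ndarray, config: EAConfig, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(N_GENES) < config.mutation_prob
    noise = rng.normal(0.0, config.mutation_sigma, size=N_GENES)
    return np.clip(genome + mask * noise, 0.0, 1.0)


def _crossover(
    g1: np.ndarray, g2: np.ndarray, config: EAConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if rng.random() < config.crossover_prob:
        mask = rng.random(N_GENES) < 0.5
        c1 = np.where(mask, g2, g1)
        c2 = np.where(mask, g1, g2)
        return c1, c2
    return g1.copy(), g2.copy()


def _evaluate(pending: list[Individual], evaluator: Evaluator, n_workers: int) -> None:
    todo = [ind for ind in pending if ind.fitness is None]
    if not todo:
        return
    if n_workers > 1:
        from joblib import Parallel, delayed

        reports = Parallel(n_jobs=n_workers)(
            delayed(evaluator)(ind.genome, ind.eval_seed) for ind in todo
        )
    else:
        reports = [evaluator(ind.genome, ind.eval_seed) for ind in todo]
    for ind, rep in zip(todo, reports):
        ind.fitness = rep


def evolve_generation(
    parents: list[Individual],
    config: EAConfig,
    evaluator: Evaluator,
    rng: np.random.Generator,
    uid_counter: int,
) -> tuple[list[Individual], int]:
    """Produce, evaluate and elitism-correct one offspring generation.

    Returns the new parent population and the advanced uid counter.
    """
    offspring: list[Individual] = []
    while len(offspring) < config.lam:
        p1 = _tournament(parents, rng, config.tournament_size)
        p2 = _tournament(parents, rng, config.tournament_size)
        c1, c2 = _crossover(p1.genome, p2.genome, config, rng)
        for child_genome in (c1, c2):
            if len(offspring) >= config.lam:
                break
            genome = _mutate(child_genome, config, rng)
            offspring.append(
                Individual(
                    genome=genome,
                    eval_seed=_eval_seed(config.seed, uid_counter),
                    uid=uid_counter,
                )
            )
            uid_counter += 1
    _evaluate(offspring, evaluator, config.n_workers)
    # Weak elitism: the best parent replaces the worst offspring.
    best_parent = max(parents, key=lambda ind: ind.total)
    worst_idx = int(np.argmin([ind.total for ind in offspring]))
    offspring[worst_idx] = best_parent
    return offspring, uid_counter


def run_ea(config: EAConfig, evaluator: Evaluator) -> EAResult:
    """Run the full loop: initialize, iterate generations, stop, report.

    The log holds one row per (generation, individual) with the three
    fitness components, constraint-violation count, total, and the total
    normalized by the generation's best.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 0xEA)))
    uid = 0
    parents: list[Individual] = []
    for _ in range(config.mu):
        parents.append(
            Individual(
                genome=random_genome(rng),
                eval_seed=_eval_seed(config.seed, uid),
                uid=uid,
            )
        )
        uid += 1
    _evaluate(parents, evaluator, config.n_workers)

    log: list[dict] = []

    def log_population(generation: int, population: list[Individual]) -> None:
        gen_best = max(ind.total for ind in population)
        for ind in population:
            rep = ind.fitness
            assert rep is not None
            rep.normalized = rep.total / gen_best
            log.append(
                {
                    "generation": generation,
                    "individual": ind.uid,
                    "decorr": rep.decorr,
                    "gauss": rep.gauss,
                    "max_rate": rep.max_rate,
                    "violations": rep.n_violations,
                    "total": rep.total,
                    "normalized": rep.normalized,
                }
            )

    log_population(0, parents)
    best = max(parents, key=lambda ind: ind.total)
    stall = 0
    generation = 0
    stop_reason = "max_generations"
    while generation < config.stop_max:
        generation += 1
        parents, uid = evolve_generation(parents, config, evaluator, rng, uid)
        log_population(generation, parents)
        gen_best = max(parents, key=lambda ind: ind.total)
        if gen_best.total > best.total:
            best = gen_best
            stall = 0
        else:
            stall += 1
        if stall >= config.stop_stall:
            stop_reason = "stalled"
            break
    return EAResult(best=best, generations=generation, log=log, stop_reason=stop_reason)
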