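"""Genetic-algorithm feature-subset selection with criterion-based fitness.

Chromosomes are binary inclusion masks over the feature columns.  Two
stock configurations mirror the study design: GA1 (crossover 0.8, mutation
0.3, fixed single-point crossover) and GA2 (crossover 0.6, mutation 0.001,
a dynamic scheme cycling single-point → two-point → uniform by generation).
Selection is roulette-wheel on rank-scaled fitness (information criteria
are unbounded below, so raw values cannot be used as weights); elitism
carries the best chromosomes through unchanged, which makes the best-ever
fitness trace monotone non-worsening.  The GA always minimizes: criteria
are used as-is, AUC and accuracy are negated.

The default objective is (negated) cross-validated AUC.  The information
criteria remain selectable as objectives, but note that for empirical
classifier ROC curves their lack-of-fit term rewards near-diagonal curves
(r close to 1), i.e. *weak* classifiers — see the methods notes — so they
are not suitable for recovering informative features.

The intersection of the masks selected by GA1 and GA2 gives a consensus
subset; an empty intersection is reported as such, never repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .classify import FeatureTable, evaluate_classifier

__all__ = [
    "Chromosome",
    "GAConfig",
    "GAResult",
    "ga1_config",
    "ga2_config",
    "init_population",
    "fitness",
    "select_parents",
    "crossover",
    "mutate",
    "run_ga",
    "intersect_masks",
]

FITNESS_CHOICES = ("icomp_roc", "aic_roc", "auc", "accuracy")


@dataclass(eq=False)
class Chromosome:
    """A binary feature-inclusion mask with (optionally) its evaluated fitness."""

    mask: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1 or self.mask.size < 1:
            raise ValueError("mask must be a nonempty 1-D binary vector")

    def copy(self) -> "Chromosome":
        return Chromosome(mask=self.mask.copy(), fitness=self.fitness)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class GAConfig:
    generations: int = 50
    pop_size: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.3
    scheme: str = "fixed"  # "fixed" (single-point) | "dynamic" (3-operator cycle)
    elitism: int = 1
    seed: int = 0
    fitness_spec: str = "auc"
    classifier: str = "LR"
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.crossover_prob <= 1.0 and 0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.scheme not in ("fixed", "dynamic"):
            raise ValueError("scheme must be 'fixed' or 'dynamic'")
        if self.fitness_spec not in FITNESS_CHOICES:
            raise ValueError(f"fitness_spec must be one of {FITNESS_CHOICES}")


def ga1_config(**overrides) -> GAConfig:
    """The fixed-crossover configuration (crossover 0.8, mutation 0.3)."""
    return replace(GAConfig(crossover_prob=0.8, mutation_prob=0.3, scheme="fixed"), **overrides)


def ga2_config(**overrides) -> GAConfig:
    """The dynamic-crossover configuration (crossover 0.6, mutation 0.001)."""
    return replace(GAConfig(crossover_prob=0.6, mutation_prob=0.001, scheme="dynamic"), **overrides)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def init_population(d: int, config: GAConfig, rng: np.random.Generator | None = None) -> list[Chromosome]:
    """``pop_size`` chromosomes with independent Bernoulli(0.5) bits, all-zero masks repaired."""
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = rng or np.random.default_rng(config.seed)
    return [
        Chromosome(_repair(rng.random(d) < 0.5, rng)) for _ in range(config.pop_size)
    ]


def fitness(chrom: Chromosome, table: FeatureTable, config: GAConfig) -> float:
    """Evaluate the configured criterion on the masked feature subset.

    The GA minimizes, so AUC and accuracy are negated; a classifier failure
    scores +inf (worst possible).
    """
    if not chrom.mask.any():
        raise ValueError("cannot evaluate an empty mask")
    try:
        report = evaluate_classifier(
            table.subset(chrom.mask), config.classifier, k=config.cv_folds, seed=config.seed
        )
    except Exception:  # noqa: BLE001 - any model failure demotes the mask
        return float("inf")
    if config.fitness_spec == "icomp_roc":
        return report.icomp_roc
    if config.fitness_spec == "aic_roc":
        return report.aic_roc
    if config.fitness_spec == "auc":
        return -report.auc
    return -report.accuracy


def select_parents(
    population: list[Chromosome], rng: np.random.Generator, n_pairs: int
) -> list[tuple[Chromosome, Chromosome]]:
    """Roulette-wheel parent sampling on rank-scaled fitness, with replacement.

    Ranks are used instead of raw fitness because the criteria are unbounded
    below; the best chromosome gets weight ``pop_size`` down to 1 for the
    worst, so a strictly best individual always has the highest selection
    probability and uniform fitness gives uniform weights.
    """
    if any(c.fitness is None for c in population):
        raise ValueError("all fitnesses must be evaluated before selection")
    m = len(population)
    ranks = rankdata([c.fitness for c in population], method="average")
    weights = m + 1.0 - ranks  # best (lowest fitness) -> largest; ties share
    prob = weights / weights.sum()
    idx = rng.choice(m, size=2 * n_pairs, replace=True, p=prob)
    return [(population[idx[2 * i]], population[idx[2 * i + 1]]) for i in range(n_pairs)]


def _single_point(a: np.ndarray, b: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    cut = rng.integers(1, a.size) if a.size > 1 else 0
    return (np.concatenate([a[:cut], b[cut:]]), np.concatenate([b[:cut], a[cut:]]))


def _two_point(a: np.ndarray, b: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    if a.size < 2:
        return a.copy(), b.copy()
    lo, hi = sorted(rng.choice(a.size, size=2, replace=False))
    c, d = a.copy(), b.copy()
    c[lo:hi + 1], d[lo:hi + 1] = b[lo:hi + 1], a[lo:hi + 1]
    return c, d


def _uniform(a: np.ndarray, b: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    swap = rng.random(a.size) < 0.5
    c, d = a.copy(), b.copy()
    c[swap], d[swap] = b[swap], a[swap]
    return c, d


_DYNAMIC_CYCLE = (_single_point, _two_point, _uniform)


def crossover(
    pair: tuple[Chromosome, Chromosome],
    config: GAConfig,
    generation: int,
    rng: np.random.Generator,
) -> tuple[Chromosome, Chromosome]:
    """Recombine a parent pair with probability ``crossover_prob``.

    The fixed scheme is single-point; the dynamic scheme cycles
    single-point, two-point and uniform operators by generation index.
    """
    a, b = pair[0].mask, pair[1].mask
    if rng.random() >= config.crossover_prob:
        return pair[0].copy(), pair[1].copy()
    op = _single_point if config.scheme == "fixed" else _DYNAMIC_CYCLE[generation % 3]
    c, d = op(a, b, rng)
    return Chromosome(c), Chromosome(d)


def mutate(chrom: Chromosome, config: GAConfig, rng: np.random.Generator) -> Chromosome:
    """Flip each bit independently with ``mutation_prob``; repair all-zero results."""
    flips = rng.random(chrom.mask.size) < config.mutation_prob
    mask = _repair(np.logical_xor(chrom.mask, flips), rng)
    return Chromosome(mask)


@dataclass
class GAResult:
    best: Chromosome
    best_fitness_trace: np.ndarray
    evaluations: int

    @property
    def best_mask(self) -> np.ndarray:
        return self.best.mask


def run_ga(table: FeatureTable, config: GAConfig) -> GAResult:
    """Generational GA loop with elitism; returns the best-ever chromosome.

    All stochastic operators draw from one generator seeded by the config,
    and fitness evaluations are cached by mask, so runs are reproducible and
    revisited masks cost nothing.
    """
    rng = np.random.default_rng(config.seed)
    cache: dict[bytes, float] = {}
    evaluations = 0

    def evaluate(chrom: Chromosome) -> None:
        nonlocal evaluations
        key = np.packbits(chrom.mask).tobytes()
        if key not in cache:
            cache[key] = fitness(chrom, table, config)
            evaluations += 1
        chrom.fitness = cache[key]

    population = init_population(table.d, config, rng)
    for chrom in population:
        evaluate(chrom)
    best = min(population, key=lambda c: c.fitness).copy()
    trace = [best.fitness]

    for gen in range(config.generations):
        population.sort(key=lambda c: c.fitness)
        elite = [c.copy() for c in population[: config.elitism]]
        n_pairs = (config.pop_size - len(elite) + 1) // 2
        offspring: list[Chromosome] = []
        for pair in select_parents(population, rng, n_pairs):
            for child in crossover(pair, config, gen, rng):
                offspring.append(mutate(child, config, rng))
        population = elite + offspring[: config.pop_size - len(elite)]
        for chrom in population:
            evaluate(chrom)
        gen_best = min(population, key=lambda c: c.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best.copy()
        trace.append(best.fitness)

    return GAResult(best=best, best_fitness_trace=np.asarray(trace), evaluations=evaluations)


def intersect_masks(m1: Chromosome, m2: Chromosome) -> tuple[Chromosome, bool]:
    """Bitwise AND of two masks; the flag reports an empty intersection."""
    if m1.mask.size != m2.mask.size:
        raise ValueError("masks must have equal length")
    both = np.logical_and(m1.mask, m2.mask)
    return Chromosome(both), bool(not both.any())
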