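"""Genetic algorithm over the mixed control-factor space.

A chromosome is (A, B, C, D) with A continuous in [1, 3] and B, C, D
discrete levels in {1, 2, 3}.  Fitness is the total performance
TP = d1 * d2^2 predicted by the surrogate, aggregated over the four
(signal, noise) combinations.  Operators: tournament selection (size 3),
blend crossover on A plus uniform level swap on the discrete genes,
Gaussian perturbation on A (sigma 0.1, clamped) plus level re-draw on the
discrete genes, and elitism of one.  Defaults follow the study settings:
1000 generations, population 80, crossover rate 0.5, mutation rate 0.08.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .config import GASettings
from .desirability import total_performance
from .errors import InvalidParameterError
from .surrogate import SurrogateModel, predict

__all__ = ["Chromosome", "Optimum", "evaluate_fitness", "optimize", "surrogate_fitness"]

SIGNAL_NOISE_GRID = ((1, 350.0), (1, 425.0), (2, 350.0), (2, 425.0))


@dataclass(frozen=True)
class Chromosome:
    factor_A: float
    factor_B: int
    factor_C: int
    factor_D: int

    def __post_init__(self) -> None:
        if not 1.0 <= self.factor_A <= 3.0:
            raise InvalidParameterError(f"factor_A out of [1, 3]: {self.factor_A}")
        for name in ("factor_B", "factor_C", "factor_D"):
            if getattr(self, name) not in (1, 2, 3):
                raise InvalidParameterError(f"{name} must be 1, 2 or 3")


@dataclass
class Optimum:
    setting: Chromosome
    tp: float
    history: list[float]  # best fitness per generation (non-decreasing)


def evaluate_fitness(
    chromosome: Chromosome,
    model: SurrogateModel,
    aggregation: str = "mean",
    signal_noise: Sequence[tuple[int, float]] = SIGNAL_NOISE_GRID,
) -> float:
    """TP of a chromosome under the surrogate.

    (d1, d2) is predicted at each (signal, noise) combination and
    aggregated — ``mean`` (default), ``worst`` (minimum, a conservative
    robustness reading) or ``nominal`` (2 physicians, regular-day rate) —
    before forming TP = d1 * d2^2.
    """
    pairs = [
        predict(model, m, z, chromosome.factor_A, chromosome.factor_B,
                chromosome.factor_C, chromosome.factor_D)
        for (m, z) in signal_noise
    ]
    if aggregation == "mean":
        d1 = float(np.mean([p[0] for p in pairs]))
        d2 = float(np.mean([p[1] for p in pairs]))
    elif aggregation == "worst":
        d1 = min(p[0] for p in pairs)
        d2 = min(p[1] for p in pairs)
    elif aggregation == "nominal":
        nominal = max(signal_noise, key=lambda mz: (mz[0], -mz[1]))
        d1, d2 = pairs[list(signal_noise).index(nominal)]
    else:
        raise InvalidParameterError(f"unknown aggregation {aggregation!r}")
    return total_performance(d1, d2)


def surrogate_fitness(
    model: SurrogateModel,
    aggregation: str = "mean",
    signal_noise: Sequence[tuple[int, float]] = SIGNAL_NOISE_GRID,
) -> Callable[[Chromosome], float]:
    return lambda chrom: evaluate_fitness(chrom, model, aggregation, signal_noise)


def _random_chromosome(rng: np.random.Generator) -> Chromosome:
    return Chromosome(
        factor_A=float(rng.uniform(1.0, 3.0)),
        factor_B=int(rng.integers(1, 4)),
        factor_C=int(rng.integers(1, 4)),
        factor_D=int(rng.integers(1, 4)),
    )


def _tournament(pop: list[Chromosome], fits: np.ndarray, rng: np.random.Generator, k: int = 3) -> Chromosome:
    idx = rng.integers(0, len(pop), size=k)
    return pop[int(idx[np.argmax(fits[idx])])]


def _crossover(a: Chromosome, b: Chromosome, rng: np.random.Generator) -> Chromosome:
    w = float(rng.random())
    new_a = float(np.clip(w * a.factor_A + (1.0 - w) * b.factor_A, 1.0, 3.0))
    pick = lambda x, y: x if rng.random() < 0.5 else y
    return Chromosome(
        factor_A=new_a,
        factor_B=pick(a.factor_B, b.factor_B),
        factor_C=pick(a.factor_C, b.factor_C),
        factor_D=pick(a.factor_D, b.factor_D),
    )


def _mutate(c: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    a, b, cc, d = c.factor_A, c.factor_B, c.factor_C, c.factor_D
    if rng.random() < rate:
        a = float(np.clip(a + rng.normal(0.0, 0.1), 1.0, 3.0))
    if rng.random() < rate:
        b = int(rng.integers(1, 4))
    if rng.random() < rate:
        cc = int(rng.integers(1, 4))
    if rng.random() < rate:
        d = int(rng.integers(1, 4))
    return Chromosome(a, b, cc, d)


def optimize(
    fitness: Callable[[Chromosome], float],
    settings: GASettings | None = None,
    seed: int = 0,
) -> Optimum:
    """Maximize ``fitness`` over the mixed factor space.

    Deterministic given ``seed``; the returned best-so-far history is
    non-decreasing because one elite survives each generation unchanged.
    """
    settings = settings or GASettings()
    if settings.population < 2:
        raise InvalidParameterError("population must be >= 2")
    rng = np.random.default_rng(seed)
    pop = [_random_chromosome(rng) for _ in range(settings.population)]
    fits = np.array([fitness(c) for c in pop])
    best_i = int(np.argmax(fits))
    best, best_fit = pop[best_i], float(fits[best_i])
    history = [best_fit]

    for _ in range(settings.generations):
        nxt: list[Chromosome] = [best]  # elitism of 1
        while len(nxt) < settings.population:
            p1 = _tournament(pop, fits, rng)
            if rng.random() < settings.crossover_rate:
                p2 = _tournament(pop, fits, rng)
                child = _crossover(p1, p2, rng)
            else:
                child = p1
            nxt.append(_mutate(child, settings.mutation_rate, rng))
        pop = nxt
        fits = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmax(fits))
        if float(fits[gen_best]) > best_fit:
            best, best_fit = pop[gen_best], float(fits[gen_best])
        history.append(best_fit)

    return Optimum(setting=best, tp=best_fit, history=history)
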