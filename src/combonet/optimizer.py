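"""Attenuation-coefficient fitting: DE/rand/1/bin and exhaustive grid search.

The objective is training classification accuracy (indeterminate calls count
as errors). The differential-evolution engine is generic over any
2-dimensional fitness so tests can inject analytic landscapes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from combonet.evaluation import accuracy, confusion
from combonet.propagation import AttenuationParams
from combonet.regnet_model import CombinationRecord, DrugActionProfile, RegulatoryNetwork
from combonet.set_distance import assess_pair

logger = logging.getLogger(__name__)

Fitness = Callable[[float, float], float]

#: generations without meaningful best-fitness improvement before stopping
CONVERGENCE_WINDOW = 10


@dataclass(frozen=True)
class DEConfig:
    """DE/rand/1/bin control parameters."""

    population_size: int = 50
    mutation_factor: float = 0.6
    crossover_rate: float = 0.9
    max_generations: int = 100
    convergence_threshold: float = 1e-6
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 3.0), (1.0, 3.0))
    seed: int = 0
    hop_max: int = 2

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (mutation needs 3 distinct others)")
        if not 0 < self.crossover_rate <= 1:
            raise ValueError(f"crossover_rate must be in (0, 1], got {self.crossover_rate}")
        if self.mutation_factor <= 0:
            raise ValueError(f"mutation_factor must be > 0, got {self.mutation_factor}")
        for lo, hi in self.bounds:
            if lo < 1:
                raise ValueError("lower bounds must be >= 1 (coefficients attenuate)")
            if hi < lo:
                raise ValueError("upper bound below lower bound")


@dataclass
class DEResult:
    best_params: AttenuationParams
    best_fitness: float
    history: list[tuple[float, float]] = field(default_factory=list)  # (best, mean) per generation
    generations_run: int = 0
    converged: bool = False


def accuracy_fitness(
    train: Sequence[CombinationRecord],
    network: RegulatoryNetwork,
    profiles: Mapping[str, DrugActionProfile],
    hop_max: int = 2,
) -> Fitness:
    """Fitness = training accuracy of the sign-rule classifier."""
    if not train:
        raise ValueError("training set is empty")
    missing = {d for r in train for d in (r.drug_a, r.drug_b)} - set(profiles)
    if missing:
        raise ValueError(f"no action profile for drug(s): {sorted(missing)}")

    def fitness(delta_pos: float, delta_neg: float) -> float:
        params = AttenuationParams(delta_pos=delta_pos, delta_neg=delta_neg, hop_max=hop_max)
        calls = [
            assess_pair(network, profiles[r.drug_a], profiles[r.drug_b], params).call
            for r in train
        ]
        return accuracy(confusion(calls, [r.label for r in train]))

    return fitness


def de_maximize(fitness: Fitness, config: DEConfig) -> DEResult:
    """Classical DE/rand/1/bin with clipping to bounds and greedy selection.

    Deterministic given ``config.seed``. Stops early once the best fitness
    has improved by less than the convergence threshold over the last
    ``CONVERGENCE_WINDOW`` generations.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    np_ = config.population_size
    pop = rng.uniform(lo, hi, size=(np_, 2))
    fit = np.array([fitness(*x) for x in pop])

    history: list[tuple[float, float]] = []
    best_trace: list[float] = []
    converged = False
    generation = 0
    for generation in range(1, config.max_generations + 1):
        for i in range(np_):
            r1, r2, r3 = rng.choice([k for k in range(np_) if k != i], size=3, replace=False)
            mutant = pop[r1] + config.mutation_factor * (pop[r2] - pop[r3])
            mutant = np.clip(mutant, lo, hi)
            cross = rng.random(2) < config.crossover_rate
            cross[rng.integers(2)] = True  # one forced dimension
            trial = np.where(cross, mutant, pop[i])
            trial_fit = fitness(*trial)
            if trial_fit > fit[i]:  # ties keep the incumbent
                pop[i] = trial
                fit[i] = trial_fit
        history.append((float(fit.max()), float(fit.mean())))
        best_trace.append(float(fit.max()))
        if (
            len(best_trace) > CONVERGENCE_WINDOW
            and best_trace[-1] - best_trace[-1 - CONVERGENCE_WINDOW] < config.convergence_threshold
        ):
            converged = True
            break

    best_idx = int(fit.argmax())
    best = pop[best_idx]
    logger.info(
        "DE finished after %d generation(s): best fitness %.6f at (%.4f, %.4f)",
        generation, fit[best_idx], best[0], best[1],
    )
    return DEResult(
        best_params=AttenuationParams(
            delta_pos=float(best[0]), delta_neg=float(best[1]), hop_max=config.hop_max
        ),
        best_fitness=float(fit[best_idx]),
        history=history,
        generations_run=len(history),
        converged=converged,
    )


def optimize_delta(
    train: Sequence[CombinationRecord],
    network: RegulatoryNetwork,
    profiles: Mapping[str, DrugActionProfile],
    config: DEConfig | None = None,
) -> DEResult:
    """Fit (delta_pos, delta_neg) by DE against training accuracy."""
    if config is None:
        config = DEConfig()
    return de_maximize(accuracy_fitness(train, network, profiles, config.hop_max), config)


@dataclass
class GridSearchResult:
    surface: dict[tuple[float, float], float]
    best_params: AttenuationParams
    best_fitness: float


def grid_search_delta(
    train: Sequence[CombinationRecord],
    network: RegulatoryNetwork,
    profiles: Mapping[str, DrugActionProfile],
    grid: tuple[Sequence[float], Sequence[float]],
    hop_max: int = 2,
) -> GridSearchResult:
    """Exhaustive accuracy surface over the given coefficient grids.

    Ties at the maximum break toward the lexicographically smaller
    (delta_pos, delta_neg).
    """
    grid_pos, grid_neg = grid
    if not len(grid_pos) or not len(grid_neg):
        raise ValueError("grids must be non-empty")
    fitness = accuracy_fitness(train, network, profiles, hop_max)
    surface = {
        (float(dp), float(dn)): fitness(dp, dn)
        for dp, dn in itertools.product(sorted(grid_pos), sorted(grid_neg))
    }
    best = max(surface.items(), key=lambda kv: (kv[1], (-kv[0][0], -kv[0][1])))
    return GridSearchResult(
        surface=surface,
        best_params=AttenuationParams(delta_pos=best[0][0], delta_neg=best[0][1], hop_max=hop_max),
        best_fitness=best[1],
    )
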