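"""Hybrid firefly / differential-evolution optimizer, plus a plain-FA baseline.

Each iteration of the hybrid method (``run_efa``) performs:

1. a full pairwise firefly pass — every candidate attempts a move toward
   every fitter neighbour, with attraction decaying in distance;
2. a partition of the population by fitness into *potential* (fittest) and
   *weak* halves;
3. a differential-evolution step (difference-vector mutation, binomial
   crossover, greedy selection) on the potential half; and
4. randomized re-population of the weak half around the current best
   vector.

The plain baseline (``run_fa``) performs only step 1.  All randomness flows
from a single seeded generator in a fixed call order, so runs are exactly
replayable.  Candidates are kept inside the search box by projection
(clipping) after every operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import TimeSeriesDataset
from .models import ModelSpec
from .objective import Objective

__all__ = [
    "EFAConfig",
    "Population",
    "FitResult",
    "init_population",
    "attraction",
    "firefly_move",
    "partition_population",
    "weak_update",
    "de_mutate",
    "de_crossover",
    "de_select",
    "minimize",
    "run_efa",
    "run_fa",
]


@dataclass
class EFAConfig:
    """Hyperparameters of the firefly/DE hybrid.

    ``bounds`` is an (M, 2) array of per-dimension [LB, UB].  ``beta0`` is
    the attractiveness at zero distance, ``phi`` the light-absorption
    coefficient, ``alpha`` the randomization weight, ``mr``/``cr`` the DE
    mutation and crossover rates, ``weak_width`` the re-seeding width of
    the weak-half update as a fraction of the box, and ``eval_mode`` how
    often fitness is refreshed during the firefly pass ("move": after each
    accepted move; "sweep": once per firefly per sweep, the canonical FA
    schedule).  ``fitness_threshold`` optionally stops the run early once
    the best fitness drops below it.
    """

    np_size: int = 20
    max_iter: int = 100
    bounds: np.ndarray | Sequence = ((0.0, 1.0),)
    seed: int = 0
    beta0: float = 1.0
    phi: float = 1.0
    alpha: float = 0.2
    mr: float = 0.5
    cr: float = 0.9
    potential_fraction: float = 0.5
    weak_width: float = 0.1
    fitness_threshold: float | None = None
    eval_mode: str = "move"

    def __post_init__(self):
        self.bounds = np.atleast_2d(np.asarray(self.bounds, float))
        if self.bounds.ndim != 2 or self.bounds.shape[1] != 2:
            raise ValueError("bounds must be an (M, 2) array")
        if not np.all(np.isfinite(self.bounds)):
            raise ValueError("bounds must be finite")
        if np.any(self.bounds[:, 0] > self.bounds[:, 1]):
            raise ValueError("lower bound exceeds upper bound")
        if self.np_size < 4:
            raise ValueError("population size must be at least 4")
        if not (0.0 <= self.mr <= 1.0 and 0.0 <= self.cr <= 1.0):
            raise ValueError("mr and cr must lie in [0, 1]")
        if not (0.0 < self.potential_fraction < 1.0):
            raise ValueError("potential_fraction must lie strictly in (0, 1)")
        if min(self.beta0, self.phi, self.alpha) < 0:
            raise ValueError("beta0, phi and alpha must be non-negative")
        if self.eval_mode not in ("move", "sweep"):
            raise ValueError("eval_mode must be 'move' or 'sweep'")

    @property
    def n_dim(self) -> int:
        return self.bounds.shape[0]

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.bounds[:, 0], self.bounds[:, 1])


@dataclass
class Population:
    """The firefly swarm: candidate vectors, their fitness, and the best."""

    members: np.ndarray  # (NP, M)
    fitness: np.ndarray  # (NP,)
    best_index: int = 0

    @property
    def best(self) -> tuple[np.ndarray, float]:
        return self.members[self.best_index], float(self.fitness[self.best_index])

    def update_best(self) -> None:
        self.best_index = int(np.argmin(self.fitness))


@dataclass
class FitResult:
    """Outcome of an optimizer run."""

    best_params: np.ndarray
    best_fitness: float
    trace: np.ndarray  # per-iteration best fitness, non-increasing
    evaluations: int
    seed: int
    algorithm: str
    config: EFAConfig
    iterations: int = 0


def init_population(
    config: EFAConfig, objective: Callable[[np.ndarray], float], rng: np.random.Generator
) -> Population:
    """Uniform initialization inside the box: x_id = LB_d + C1 (UB_d - LB_d)."""
    lb, ub = config.bounds[:, 0], config.bounds[:, 1]
    c1 = rng.random((config.np_size, config.n_dim))
    members = lb + c1 * (ub - lb)
    fitness = np.array([objective(m) for m in members])
    pop = Population(members=members, fitness=fitness)
    pop.update_best()
    return pop


def attraction(r: float, config: EFAConfig) -> float:
    """Attractiveness beta = beta0 * exp(-phi * r^2); non-increasing in r."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    return config.beta0 * math.exp(-config.phi * r * r)


def firefly_move(
    x_i: np.ndarray,
    x_j: np.ndarray,
    j_i: float,
    j_j: float,
    config: EFAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move x_i toward a brighter neighbour x_j; no-op if x_j is not fitter.

    x_i <- x_i + beta (x_j - x_i) + alpha (C2 - 0.5), C2 fresh uniform per
    component, then projected onto the box.
    """
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    if x_i.shape != x_j.shape:
        raise ValueError("vectors must have equal length")
    if not j_j < j_i:
        return x_i
    r = float(np.linalg.norm(x_j - x_i))
    beta = attraction(r, config)
    c2 = rng.random(x_i.shape)
    moved = x_i + beta * (x_j - x_i) + config.alpha * (c2 - 0.5)
    return config.clip(moved)


def partition_population(pop: Population, config: EFAConfig) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the potential (fittest) and weak members.

    Stable sort by fitness, ties broken by original index; the first
    ceil(potential_fraction * NP) are potential.
    """
    order = np.argsort(pop.fitness, kind="stable")
    n_pot = math.ceil(config.potential_fraction * len(pop.fitness))
    return order[:n_pot], order[n_pot:]


def weak_update(
    x_min: np.ndarray, config: EFAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Re-seed a weak member around the current best vector.

    x_id <- x_min,d + (C3 - 0.5) * w * (UB_d - LB_d) with C3 fresh uniform
    per component and w the configurable re-seeding width; clipped to the
    box.  With w = 0 the member jumps exactly onto x_min.
    """
    lb, ub = config.bounds[:, 0], config.bounds[:, 1]
    c3 = rng.random(np.shape(x_min))
    return config.clip(x_min + (c3 - 0.5) * config.weak_width * (ub - lb))


def de_mutate(
    potential: np.ndarray, i: int, config: EFAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Difference-vector mutation within the potential set.

    v_i = x_i + C4 * MR * (x_r1 - x_r2) with r1 != r2 != i drawn uniformly
    from the potential set and C4 a fresh uniform scalar; clipped.
    """
    n = len(potential)
    if n < 4:
        raise ValueError("mutation needs at least 4 potential members")
    candidates = [k for k in range(n) if k != i]
    r1, r2 = rng.choice(candidates, size=2, replace=False)
    c4 = rng.random()
    v = potential[i] + c4 * config.mr * (potential[r1] - potential[r2])
    return config.clip(v)


def de_crossover(
    x_i: np.ndarray, v_i: np.ndarray, config: EFAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover with one forced index.

    Component d takes v_i,d when a fresh uniform draw is <= CR or d is the
    forced index j_rand; otherwise it keeps x_i,d.
    """
    x_i = np.asarray(x_i, float)
    v_i = np.asarray(v_i, float)
    if x_i.shape != v_i.shape:
        raise ValueError("vectors must have equal length")
    draws = rng.random(x_i.shape)
    j_rand = rng.integers(x_i.size)
    take = draws <= config.cr
    take.flat[j_rand] = True
    return np.where(take, v_i, x_i)


def de_select(
    x_i: np.ndarray,
    j_i: float,
    x_off: np.ndarray,
    objective: Callable[[np.ndarray], float],
) -> tuple[np.ndarray, float]:
    """Greedy selection: the offspring survives only on strict improvement."""
    j_off = objective(x_off)
    if j_off < j_i:
        return x_off, j_off
    return x_i, j_i


def _firefly_sweep(
    pop: Population,
    config: EFAConfig,
    objective: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> None:
    """One full pairwise pass: each i attempts a move toward every fitter j."""
    n = len(pop.fitness)
    for i in range(n):
        moved = False
        for j in range(n):
            if pop.fitness[j] < pop.fitness[i]:
                pop.members[i] = firefly_move(
                    pop.members[i], pop.members[j],
                    pop.fitness[i], pop.fitness[j], config, rng,
                )
                moved = True
                if config.eval_mode == "move":
                    pop.fitness[i] = objective(pop.members[i])
        if moved and config.eval_mode == "sweep":
            pop.fitness[i] = objective(pop.members[i])


def minimize(
    objective: Callable[[np.ndarray], float],
    config: EFAConfig,
    *,
    hybrid: bool = True,
) -> FitResult:
    """Run the hybrid (or plain-FA) loop on an arbitrary objective.

    Elitism is explicit: the best-so-far vector and fitness are tracked
    outside the population, so the returned trace is non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    evals = [0]

    def counted(x):
        evals[0] += 1
        return objective(x)

    pop = init_population(config, counted, rng)
    best_x, best_f = pop.best
    best_x = best_x.copy()
    trace = []
    iterations = 0

    for _ in range(config.max_iter):
        iterations += 1
        _firefly_sweep(pop, config, counted, rng)

        if hybrid:
            pot_idx, weak_idx = partition_population(pop, config)
            if len(pot_idx) >= 4:
                potential = pop.members[pot_idx].copy()
                for local_i, gi in enumerate(pot_idx):
                    v = de_mutate(potential, local_i, config, rng)
                    off = de_crossover(potential[local_i], v, config, rng)
                    pop.members[gi], pop.fitness[gi] = de_select(
                        potential[local_i], pop.fitness[gi], off, counted
                    )
            pop.update_best()
            x_min = pop.members[pop.best_index].copy()
            for gi in weak_idx:
                pop.members[gi] = weak_update(x_min, config, rng)
                pop.fitness[gi] = counted(pop.members[gi])

        pop.update_best()
        cur_x, cur_f = pop.best
        if cur_f < best_f:
            best_f = cur_f
            best_x = cur_x.copy()
        trace.append(best_f)
        if config.fitness_threshold is not None and best_f <= config.fitness_threshold:
            break

    return FitResult(
        best_params=best_x,
        best_fitness=float(best_f),
        trace=np.array(trace),
        evaluations=evals[0],
        seed=config.seed,
        algorithm="efa" if hybrid else "fa",
        config=config,
        iterations=iterations,
    )


def run_efa(
    model: ModelSpec,
    data: TimeSeriesDataset,
    config: EFAConfig,
    *,
    free: np.ndarray | None = None,
    template: np.ndarray | None = None,
) -> FitResult:
    """Fit ``model`` to ``data`` with the firefly/DE hybrid.

    ``free``/``template`` restrict the search to a subset of parameters,
    clamping the rest (used for single-parameter recovery studies and for
    knockout variants whose zeroed rates must stay fixed).
    """
    obj = Objective(model, data, free=free, template=template)
    result = minimize(obj, config, hybrid=True)
    result.best_params = obj.full_params(result.best_params)
    return result


def run_fa(
    model: ModelSpec,
    data: TimeSeriesDataset,
    config: EFAConfig,
    *,
    free: np.ndarray | None = None,
    template: np.ndarray | None = None,
) -> FitResult:
    """Plain firefly baseline: pairwise moves only, no DE step, no re-seeding."""
    obj = Objective(model, data, free=free, template=template)
    result = minimize(obj, config, hybrid=False)
    result.best_params = obj.full_params(result.best_params)
    return result
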