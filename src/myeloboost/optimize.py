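"""Bounded-box maximization metaheuristics: DE, PSO, GA and SA.

All four optimizers share one contract: maximize a scalar objective over
a box-constrained continuous search space, under a fixed evaluation
budget, with every stochastic draw flowing from a single seeded
generator so runs are bit-reproducible.  Positions that arithmetic
pushes outside the box are projected (clipped) back onto it.

Each run returns an :class:`OptimizerResult` holding the best candidate,
the best-so-far fitness trace (entry 0 is the best of the initial
population / starting point, then one entry per iteration), and the
number of objective evaluations spent.

Algorithms:

* **DE** — classic DE/rand/1/bin: mutant ``x_r1 + F (x_r2 - x_r3)``,
  binomial crossover with one guaranteed-inherited coordinate, greedy
  one-to-one selection (ties broken by a fair coin).
* **PSO** — inertia-weight velocity update with fresh uniform draws per
  component and term; velocities start at zero and are clamped to the
  box width.
* **GA** — rank-based parent selection, one-point crossover, per-gene
  uniform-resample mutation, elitism plus a random-admission quota.
* **SA** — single chain, uniform box-scaled perturbations, Metropolis
  acceptance ``exp(dF / T)`` for downhill moves, geometric cooling;
  reports the best state ever visited, not the final one.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Dimension",
    "SearchSpace",
    "Candidate",
    "OptimizerResult",
    "DEConfig",
    "PSOConfig",
    "GAConfig",
    "SAConfig",
    "ObjectiveError",
    "project_to_bounds",
    "de_optimize",
    "pso_optimize",
    "ga_optimize",
    "sa_optimize",
    "OPTIMIZERS",
]

Objective = Callable[[np.ndarray], float]


class ObjectiveError(RuntimeError):
    """The objective raised; carries the candidate that triggered it."""

    def __init__(self, position: np.ndarray, cause: BaseException):
        super().__init__(f"objective failed at {np.asarray(position)!r}: "
                         f"{cause}")
        self.position = np.asarray(position)
        self.cause = cause


@dataclasses.dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"dimension {self.name!r}: lower must be < "
                             f"upper ({self.lower} vs {self.upper})")


@dataclasses.dataclass(frozen=True)
class SearchSpace:
    dims: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.dims]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")

    @classmethod
    def from_bounds(cls, bounds: Sequence[tuple[str, float, float]] |
                    Sequence[Dimension]) -> "SearchSpace":
        dims = tuple(d if isinstance(d, Dimension) else Dimension(*d)
                     for d in bounds)
        return cls(dims)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dims)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dims], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dims], dtype=float)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def __len__(self) -> int:
        return len(self.dims)

    def sample(self, rng: np.random.Generator,
               n: Optional[int] = None) -> np.ndarray:
        size = len(self.dims) if n is None else (n, len(self.dims))
        return rng.uniform(self.lower, self.upper, size=size)

    def contains(self, position: np.ndarray, atol: float = 1e-12) -> bool:
        x = np.asarray(position, dtype=float)
        return bool(np.all(x >= self.lower - atol)
                    and np.all(x <= self.upper + atol))


@dataclasses.dataclass
class Candidate:
    position: np.ndarray
    fitness: Optional[float] = None


@dataclasses.dataclass
class OptimizerResult:
    best: Candidate
    trace: list[float]
    evaluations: int
    runtime: float

    def __post_init__(self) -> None:
        if any(b > a for a, b in zip(self.trace[1:], self.trace)):
            raise AssertionError("best-so-far trace must be non-decreasing")


@dataclasses.dataclass(frozen=True)
class DEConfig:
    F: float = 0.5
    CR: float = 0.9
    NP: int = 10
    generations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be > 0")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must be in [0, 1]")
        if self.NP < 4:
            raise ValueError("NP must be >= 4 (three distinct donors + "
                             "target)")


@dataclasses.dataclass(frozen=True)
class PSOConfig:
    omega: float = 0.5
    c1: float = 2.05
    c2: float = 2.05
    swarm: int = 10
    iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration coefficients must be >= 0")
        if self.swarm < 1:
            raise ValueError("swarm must be >= 1")


@dataclasses.dataclass(frozen=True)
class GAConfig:
    pop_size: int = 10
    generations: int = 10
    elitism_fraction: float = 0.3
    random_selection_fraction: float = 0.1
    mutation_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("elitism_fraction", "random_selection_fraction",
                     "mutation_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elitism_fraction + self.random_selection_fraction > 1.0:
            raise ValueError("elitism + random selection must be <= 1")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")


@dataclasses.dataclass(frozen=True)
class SAConfig:
    T0: float = 1.0
    cooling_factor: float = 0.95
    delta: float = 0.1  # perturbation half-width as a fraction of box width
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be > 0")
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def project_to_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Clip every coordinate to its box interval."""
    x = np.asarray(position, dtype=float)
    if x.shape[-1] != len(space):
        raise ValueError(f"position has {x.shape[-1]} coordinates, "
                         f"space has {len(space)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("position contains non-finite coordinates")
    return np.clip(x, space.lower, space.upper)


def _call(objective: Objective, position: np.ndarray) -> float:
    try:
        return float(objective(position))
    except Exception as exc:  # surface the failing candidate
        raise ObjectiveError(position, exc) from exc


def de_optimize(objective: Objective, space: SearchSpace,
                cfg: DEConfig = DEConfig()) -> OptimizerResult:
    """DE/rand/1/bin maximization."""
    rng = np.random.default_rng(cfg.seed)
    start = time.perf_counter()
    pop = space.sample(rng, cfg.NP)
    fit = np.array([_call(objective, x) for x in pop])
    evals = cfg.NP
    trace = [float(fit.max())]
    d = len(space)
    for _ in range(cfg.generations):
        for i in range(cfg.NP):
            r1, r2, r3 = rng.choice(
                [j for j in range(cfg.NP) if j != i], size=3, replace=False)
            mutant = project_to_bounds(
                pop[r1] + cfg.F * (pop[r2] - pop[r3]), space)
            cross = rng.uniform(size=d) < cfg.CR
            cross[rng.integers(d)] = True  # guaranteed-inherited coordinate
            trial = np.where(cross, mutant, pop[i])
            trial_fit = _call(objective, trial)
            evals += 1
            if trial_fit > fit[i] or (trial_fit == fit[i]
                                      and rng.uniform() < 0.5):
                pop[i], fit[i] = trial, trial_fit
        trace.append(float(fit.max()))
    best = int(np.argmax(fit))
    return OptimizerResult(Candidate(pop[best].copy(), float(fit[best])),
                           trace, evals, time.perf_counter() - start)


def pso_optimize(objective: Objective, space: SearchSpace,
                 cfg: PSOConfig = PSOConfig()) -> OptimizerResult:
    """Inertia-weight particle swarm maximization."""
    rng = np.random.default_rng(cfg.seed)
    start = time.perf_counter()
    d = len(space)
    pos = space.sample(rng, cfg.swarm)
    vel = np.zeros_like(pos)
    fit = np.array([_call(objective, x) for x in pos])
    evals = cfg.swarm
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmax(fit))
    gbest, gbest_fit = pos[g].copy(), float(fit[g])
    trace = [gbest_fit]
    vmax = space.width
    for _ in range(cfg.iterations):
        r1 = rng.uniform(size=(cfg.swarm, d))
        r2 = rng.uniform(size=(cfg.swarm, d))
        vel = (cfg.omega * vel
               + cfg.c1 * r1 * (pbest - pos)
               + cfg.c2 * r2 * (gbest - pos))
        vel = np.clip(vel, -vmax, vmax)
        pos = project_to_bounds(pos + vel, space)
        fit = np.array([_call(objective, x) for x in pos])
        evals += cfg.swarm
        improved = fit > pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trace.append(gbest_fit)
    return OptimizerResult(Candidate(gbest, gbest_fit), trace, evals,
                           time.perf_counter() - start)


def ga_optimize(objective: Objective, space: SearchSpace,
                cfg: GAConfig = GAConfig()) -> OptimizerResult:
    """Genetic algorithm with elitism, rank selection and one-point
    crossover.

    Per generation the ranked population contributes
    ``round(elitism_fraction * pop)`` unchanged elites and
    ``round(random_selection_fraction * pop)`` uniformly chosen survivors
    (both keep their fitness); the remainder are crossover offspring,
    each gene mutated with probability ``mutation_rate`` by resampling
    uniformly within its bound.
    """
    rng = np.random.default_rng(cfg.seed)
    start = time.perf_counter()
    d = len(space)
    n_elite = int(round(cfg.elitism_fraction * cfg.pop_size))
    n_random = min(int(round(cfg.random_selection_fraction * cfg.pop_size)),
                   cfg.pop_size - n_elite)
    pop = space.sample(rng, cfg.pop_size)
    fit = np.array([_call(objective, x) for x in pop])
    evals = cfg.pop_size
    g = int(np.argmax(fit))
    best_pos, best_fit = pop[g].copy(), float(fit[g])
    trace = [best_fit]
    # linear rank weights: best rank gets weight pop_size, worst gets 1
    rank_w = np.arange(cfg.pop_size, 0, -1, dtype=float)
    rank_w /= rank_w.sum()
    for _ in range(cfg.generations):
        order = np.argsort(-fit)
        pop, fit = pop[order], fit[order]
        next_pop = [pop[i].copy() for i in range(n_elite)]
        next_fit = [float(fit[i]) for i in range(n_elite)]
        if n_random:
            for i in rng.choice(cfg.pop_size, size=n_random, replace=False):
                next_pop.append(pop[i].copy())
                next_fit.append(float(fit[i]))
        while len(next_pop) < cfg.pop_size:
            pa, pb = rng.choice(cfg.pop_size, size=2, p=rank_w)
            if d > 1:
                cut = int(rng.integers(1, d))
                child = np.concatenate([pop[pa][:cut], pop[pb][cut:]])
            else:
                child = pop[pa if rng.uniform() < 0.5 else pb].copy()
            mutate = rng.uniform(size=d) < cfg.mutation_rate
            if mutate.any():
                child[mutate] = rng.uniform(space.lower[mutate],
                                            space.upper[mutate])
            next_pop.append(child)
            next_fit.append(_call(objective, child))
            evals += 1
        pop = np.array(next_pop)
        fit = np.array(next_fit)
        g = int(np.argmax(fit))
        if float(fit[g]) > best_fit:
            best_pos, best_fit = pop[g].copy(), float(fit[g])
        trace.append(best_fit)
    return OptimizerResult(Candidate(best_pos, best_fit), trace, evals,
                           time.perf_counter() - start)


def sa_optimize(objective: Objective, space: SearchSpace,
                cfg: SAConfig = SAConfig()) -> OptimizerResult:
    """Simulated annealing with Metropolis acceptance and geometric
    cooling; returns the best state ever visited."""
    rng = np.random.default_rng(cfg.seed)
    start = time.perf_counter()
    step = cfg.delta * space.width
    x = space.sample(rng)
    fx = _call(objective, x)
    evals = 1
    best, best_fit = x.copy(), fx
    trace = [fx]
    T = cfg.T0
    for _ in range(cfg.iterations):
        r = rng.uniform(-1.0, 1.0, size=len(space))
        x_new = project_to_bounds(x + step * r, space)
        f_new = _call(objective, x_new)
        evals += 1
        delta_f = f_new - fx
        if delta_f > 0 or rng.uniform() < np.exp(delta_f / T):
            x, fx = x_new, f_new
        if fx > best_fit:
            best, best_fit = x.copy(), fx
        trace.append(best_fit)
        T *= cfg.cooling_factor
    return OptimizerResult(Candidate(best, best_fit), trace, evals,
                           time.perf_counter() - start)


OPTIMIZERS = {
    "de": (de_optimize, DEConfig),
    "pso": (pso_optimize, PSOConfig),
    "ga": (ga_optimize, GAConfig),
    "sa": (sa_optimize, SAConfig),
}
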