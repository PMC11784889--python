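"""Shared containers for the bounded continuous black-box optimizers.

All optimizers in this subpackage minimise ``objective(x)`` over a hard
rectangular box. Candidate positions produced by any update rule are clipped
to the box before evaluation, and a candidate replaces its agent only when it
strictly improves the agent's fitness (greedy acceptance), which makes every
best-so-far trace non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

Objective = Callable[[np.ndarray], float]


class Agent(NamedTuple):
    """A single candidate point and its fitness (lower is better)."""

    position: np.ndarray
    fitness: float


@dataclass(frozen=True)
class Bounds:
    """A rectangular search box: ``lower[d] < upper[d]`` for every dimension."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or upper.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if not (lower < upper).all():
            raise ValueError("every lower bound must be strictly below its upper bound")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return ((x >= self.lower) & (x <= self.upper)).all(axis=1)


def evaluate_batch(objective: Objective, x: np.ndarray) -> np.ndarray:
    """Evaluate ``objective`` on the rows of ``x``.

    Objectives carrying a truthy ``batched`` attribute are called once with the
    full ``(n, d)`` matrix and must return an ``(n,)`` vector; anything else is
    called row by row.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if getattr(objective, "batched", False):
        out = np.asarray(objective(x), dtype=float)
        if out.shape != (x.shape[0],):
            raise ValueError("batched objective returned the wrong shape")
        return out
    return np.array([float(objective(row)) for row in x], dtype=float)


class Swarm:
    """An evaluated population inside a :class:`Bounds` box."""

    def __init__(self, positions: np.ndarray, fitness: np.ndarray, bounds: Bounds):
        positions = np.asarray(positions, dtype=float)
        fitness = np.asarray(fitness, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != bounds.dim:
            raise ValueError("positions must be (n_agents, dim)")
        if fitness.shape != (positions.shape[0],):
            raise ValueError("fitness must be one value per agent")
        if np.isnan(fitness).any():
            raise ValueError("swarm must be evaluated (no NaN fitness)")
        if not bounds.contains(positions).all():
            raise ValueError("all agents must lie inside the bounds")
        self.positions = positions
        self.fitness = fitness
        self.bounds = bounds

    @classmethod
    def init_random(
        cls, objective: Objective, bounds: Bounds, n: int, rng: np.random.Generator
    ) -> "Swarm":
        positions = bounds.sample(rng, n)
        return cls(positions, evaluate_batch(objective, positions), bounds)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, i: int) -> Agent:
        return Agent(self.positions[i].copy(), float(self.fitness[i]))

    @property
    def agents(self) -> list[Agent]:
        return [self[i] for i in range(len(self))]

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def best_position(self) -> np.ndarray:
        return self.positions[self.best_index].copy()

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[self.best_index])

    @property
    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def greedy_accept(self, candidates: np.ndarray, cand_fitness: np.ndarray) -> np.ndarray:
        """Replace agents whose candidate strictly improves fitness.

        Returns the boolean acceptance mask.
        """
        improved = cand_fitness < self.fitness
        self.positions[improved] = candidates[improved]
        self.fitness[improved] = cand_fitness[improved]
        return improved


@dataclass
class OptResult:
    """Outcome of one optimizer run.

    ``trace[k]`` is the best-so-far fitness after iteration ``k`` (``trace[0]``
    is the best of the initial population); it is non-increasing and its final
    entry equals ``best_fitness``, the objective value at ``best_position``.
    """

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    n_evaluations: int
    optimizer: str = ""

    def __post_init__(self) -> None:
        self.best_position = np.asarray(self.best_position, dtype=float)
        self.trace = np.asarray(self.trace, dtype=float)

    def trace_frame(self):
        """Convergence trace as a two-column DataFrame (iteration, best_fitness)."""
        import pandas as pd

        return pd.DataFrame(
            {"iteration": np.arange(self.trace.size), "best_fitness": self.trace}
        )


class BestSoFar:
    """Running archive of the best point seen, feeding the convergence trace."""

    def __init__(self) -> None:
        self.position: np.ndarray | None = None
        self.fitness = np.inf
        self.history: list[float] = []

    def update(self, swarm: Swarm) -> None:
        if swarm.best_fitness < self.fitness:
            self.fitness = swarm.best_fitness
            self.position = swarm.best_position

    def update_point(self, position: np.ndarray, fitness: float) -> None:
        if fitness < self.fitness:
            self.fitness = float(fitness)
            self.position = np.asarray(position, dtype=float).copy()

    def record(self) -> None:
        self.history.append(self.fitness)

    def result(self, n_evaluations: int, optimizer: str) -> OptResult:
        assert self.position is not None, "archive never updated"
        return OptResult(
            best_position=self.position,
            best_fitness=self.fitness,
            trace=np.asarray(self.history, dtype=float),
            n_evaluations=n_evaluations,
            optimizer=optimizer,
        )


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, ``None`` or a Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
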