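"""Chimp Optimizer (ChOA variant with fitness-ranked role groups).

The population is partitioned each iteration into contiguous rank blocks
(alpha holding the best agents, then beta, gamma, delta). The hunting phase
pulls every agent toward the global best and its own group's best with
random accelerations; the exploitation phase contracts agents toward the same
two attractors with uniform random coefficients. Both moves are clipped to
the box and accepted greedily.

``variant='canonical'`` replaces the hunting accelerations by the linearly
decaying coefficient scheme of the original ChOA publication, seeded from
``l_const``; the default ``'as_printed'`` uses fixed ``c1``/``c2`` gains and
ignores ``l_const``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._core import (
    BestSoFar,
    Bounds,
    Objective,
    OptResult,
    Swarm,
    as_rng,
    evaluate_batch,
)

logger = logging.getLogger(__name__)

ROLE_NAMES = ("alpha", "beta", "gamma", "delta")

__all__ = [
    "ChimpConfig",
    "GroupAssignment",
    "chimp_form_groups",
    "chimp_hunt",
    "chimp_exploit",
    "chimp_run",
    "hunt_candidates",
    "exploit_candidates",
]


@dataclass(frozen=True)
class ChimpConfig:
    """CO control parameters.

    w_inertia keeps part of the previous position; c1/c2 accelerate toward
    the global and group bests; the per-agent rand(), delta and eps
    coefficients are redrawn uniformly on their ranges at every use.
    ``l_const`` is only consumed by the canonical variant, as the starting
    value of its linearly decaying coefficient.
    """

    w_inertia: float = 1.0
    c1: float = 1.0
    c2: float = 1.0
    delta_range: tuple[float, float] = (0.0, 1.0)
    eps_range: tuple[float, float] = (0.0, 1.0)
    l_const: float = 2.5
    n_groups: int = 4
    pop_size: int = 50
    max_iter: int = 100
    variant: str = "as_printed"

    def __post_init__(self) -> None:
        if min(self.w_inertia, self.c1, self.c2) < 0:
            raise ValueError("w_inertia, c1 and c2 must be non-negative")
        for name, rng_pair in (("delta_range", self.delta_range), ("eps_range", self.eps_range)):
            lo, hi = rng_pair
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative interval")
        if self.n_groups < 1:
            raise ValueError("n_groups must be at least 1")
        if self.pop_size < 1 or self.max_iter < 0:
            raise ValueError("pop_size must be positive, max_iter non-negative")
        if self.variant not in ("as_printed", "canonical"):
            raise ValueError("variant must be 'as_printed' or 'canonical'")


@dataclass
class GroupAssignment:
    """Role labels per agent plus the index of each group's best member."""

    labels: np.ndarray  # int group id per agent, 0 = alpha
    group_best: np.ndarray  # per group, index of its best member

    @property
    def n_groups(self) -> int:
        return self.group_best.size

    def role_names(self) -> list[str]:
        return [
            ROLE_NAMES[g] if g < len(ROLE_NAMES) else f"group{g}"
            for g in self.labels
        ]

    def group_best_positions(self, swarm: Swarm) -> np.ndarray:
        """Per-agent position of its group's best member, shape (n_agents, dim)."""
        return swarm.positions[self.group_best[self.labels]]

    def refresh(self, swarm: Swarm) -> None:
        """Recompute group bests after positions/fitness changed (labels fixed)."""
        for g in range(self.n_groups):
            members = np.flatnonzero(self.labels == g)
            self.group_best[g] = members[np.argmin(swarm.fitness[members])]


def chimp_form_groups(swarm: Swarm, config: ChimpConfig) -> GroupAssignment:
    """Partition agents into contiguous rank blocks, best block = alpha.

    Agents are ranked by ascending fitness with ties broken by original index
    (stable sort). Block sizes differ by at most one, remainders going to the
    leading (better) groups. When there are fewer agents than groups the
    group count shrinks to the agent count.
    """
    n = len(swarm)
    n_groups = config.n_groups
    if n < n_groups:
        logger.info("shrinking n_groups from %d to %d (small swarm)", n_groups, n)
        n_groups = n
    order = np.argsort(swarm.fitness, kind="stable")
    base, extra = divmod(n, n_groups)
    sizes = [base + 1 if g < extra else base for g in range(n_groups)]
    labels = np.empty(n, dtype=int)
    group_best = np.empty(n_groups, dtype=int)
    start = 0
    for g, size in enumerate(sizes):
        block = order[start : start + size]
        labels[block] = g
        group_best[g] = block[0]  # best-ranked member of the block
        start += size
    return GroupAssignment(labels=labels, group_best=group_best)


def hunt_candidates(
    positions: np.ndarray,
    best: np.ndarray,
    group_best: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    r1: np.ndarray,
    r2: np.ndarray,
) -> np.ndarray:
    """Hunting move: w P_i + c1 r1_i (Best - P_i) + c2 r2_i (GroupBest_i - P_i)."""
    return (
        w * positions
        + c1 * r1[:, None] * (best - positions)
        + c2 * r2[:, None] * (group_best - positions)
    )


def exploit_candidates(
    positions: np.ndarray,
    best: np.ndarray,
    group_best: np.ndarray,
    delta: np.ndarray,
    eps: np.ndarray,
) -> np.ndarray:
    """Exploitation move: P_i + delta_i (Best - P_i) + eps_i (GroupBest_i - P_i)."""
    return (
        positions
        + delta[:, None] * (best - positions)
        + eps[:, None] * (group_best - positions)
    )


def _canonical_coeff(l_now: float, r: np.ndarray) -> np.ndarray:
    # ChOA-style dynamic coefficient: 2 f r - f with f decaying from l_const to 0
    return 2.0 * l_now * r - l_now


def chimp_hunt(
    swarm: Swarm,
    groups: GroupAssignment,
    config: ChimpConfig,
    objective: Objective,
    rng: np.random.Generator,
    l_now: float | None = None,
) -> Swarm:
    """Hunting phase. Draw order: r1 vector, then r2 vector (per-agent scalars)."""
    r1 = rng.uniform(size=len(swarm))
    r2 = rng.uniform(size=len(swarm))
    gb = groups.group_best_positions(swarm)
    if config.variant == "canonical":
        f = config.l_const if l_now is None else l_now
        cand = (
            config.w_inertia * swarm.positions
            + _canonical_coeff(f, r1)[:, None] * (swarm.best_position - swarm.positions)
            + _canonical_coeff(f, r2)[:, None] * (gb - swarm.positions)
        )
    else:
        cand = hunt_candidates(
            swarm.positions,
            swarm.best_position,
            gb,
            config.w_inertia,
            config.c1,
            config.c2,
            r1,
            r2,
        )
    cand = swarm.bounds.clip(cand)
    swarm.greedy_accept(cand, evaluate_batch(objective, cand))
    groups.refresh(swarm)
    return swarm


def chimp_exploit(
    swarm: Swarm,
    groups: GroupAssignment,
    config: ChimpConfig,
    objective: Objective,
    rng: np.random.Generator,
) -> Swarm:
    """Exploitation phase. Draw order: delta vector, then eps vector."""
    delta = rng.uniform(*config.delta_range, size=len(swarm))
    eps = rng.uniform(*config.eps_range, size=len(swarm))
    cand = exploit_candidates(
        swarm.positions,
        swarm.best_position,
        groups.group_best_positions(swarm),
        delta,
        eps,
    )
    cand = swarm.bounds.clip(cand)
    swarm.greedy_accept(cand, evaluate_batch(objective, cand))
    groups.refresh(swarm)
    return swarm


def chimp_run(
    objective: Objective,
    bounds: Bounds,
    config: ChimpConfig | None = None,
    rng=None,
    initial_population: np.ndarray | None = None,
    initial_fitness: np.ndarray | None = None,
) -> OptResult:
    """Full CO run: form-groups -> hunt -> exploit per iteration.

    A seeded initial population (optionally with pre-computed fitness) lets
    another optimizer hand over its final agents; the trace then starts at
    that population's best fitness. Evaluation count is
    ``pop_size * (1 + 2 * max_iter)`` when self-initialised, and
    ``pop_size * 2 * max_iter`` when both population and fitness are supplied.
    """
    config = config or ChimpConfig()
    rng = as_rng(rng)
    n_init_evals = 0
    if initial_population is not None:
        positions = np.asarray(initial_population, dtype=float)
        if not bounds.contains(positions).all():
            raise ValueError("initial_population must lie inside bounds")
        if initial_fitness is None:
            fitness = evaluate_batch(objective, positions)
            n_init_evals = positions.shape[0]
        else:
            fitness = np.asarray(initial_fitness, dtype=float)
        swarm = Swarm(positions.copy(), fitness.copy(), bounds)
    else:
        swarm = Swarm.init_random(objective, bounds, config.pop_size, rng)
        n_init_evals = config.pop_size
    archive = BestSoFar()
    archive.update(swarm)
    archive.record()
    for it in range(config.max_iter):
        groups = chimp_form_groups(swarm, config)
        frac = it / config.max_iter if config.max_iter else 0.0
        l_now = config.l_const * (1.0 - frac)
        chimp_hunt(swarm, groups, config, objective, rng, l_now=l_now)
        chimp_exploit(swarm, groups, config, objective, rng)
        archive.update(swarm)
        archive.record()
    n_evals = n_init_evals + 2 * len(swarm) * config.max_iter
    result = archive.result(n_evals, optimizer="chimp")
    result.final_swarm = swarm
    return result
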