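"""Bald Eagle Search (BES).

A three-phase swarm metaheuristic that mimics a bald eagle's hunt: the eagle
first *selects* a promising region around the best point found so far, then
*searches* that region along a spiral path built from polar-coordinate
offsets, and finally *swoops* on the prey, contracting agents toward the best
point with hyperbolic-spiral offsets.

Each phase proposes one candidate per agent, clips it to the search box,
evaluates it, and keeps it only when it improves that agent (greedy
acceptance). Two dialects of the spiral radius are provided:

``as_printed``
    the radius is multiplicative in the angle, ``r(i) = rand · R · θ(i)``;
``canonical``
    the radius of the original BES formulation, ``r(i) = θ(i) + R · rand``.

The default follows the printed form; both share every other update rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

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

__all__ = [
    "BesConfig",
    "BesPolarOffsets",
    "bes_polar_offsets",
    "bes_select_space",
    "bes_search_space",
    "bes_swoop",
    "bes_run",
    "select_candidates",
    "search_candidates",
    "swoop_candidates",
]


@dataclass(frozen=True)
class BesConfig:
    """BES control parameters.

    alpha_ctrl : exploration gain of the select phase, in [1.5, 2].
    a_angle    : spiral angle coefficient, in [5, 10].
    R_radius   : spiral radius coefficient, in [0.5, 2].
    variant    : 'as_printed' (multiplicative radius) or 'canonical'.
    """

    alpha_ctrl: float = 2.0
    a_angle: float = 10.0
    R_radius: float = 1.5
    pop_size: int = 50
    max_iter: int = 100
    variant: str = "as_printed"

    def __post_init__(self) -> None:
        if not 1.5 <= self.alpha_ctrl <= 2.0:
            raise ValueError("alpha_ctrl must lie in [1.5, 2]")
        if not 5.0 <= self.a_angle <= 10.0:
            raise ValueError("a_angle must lie in [5, 10]")
        if not 0.5 <= self.R_radius <= 2.0:
            raise ValueError("R_radius must lie in [0.5, 2]")
        if self.pop_size < 1:
            raise ValueError("pop_size must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")
        if self.variant not in ("as_printed", "canonical"):
            raise ValueError("variant must be 'as_printed' or 'canonical'")


@dataclass(frozen=True)
class BesPolarOffsets:
    """Per-agent polar offsets driving the search and swoop spirals.

    ``norm_x``/``norm_y`` are the raw spiral coordinates divided by the batch
    maximum absolute value, hence bounded by [-1, 1]; an all-zero batch
    normalises to zeros (0/0 guard).
    """

    theta: np.ndarray
    radius: np.ndarray
    raw_x: np.ndarray
    raw_y: np.ndarray
    norm_x: np.ndarray
    norm_y: np.ndarray


def _safe_norm(raw: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(raw))
    if m == 0.0:
        return np.zeros_like(raw)
    return raw / m


def bes_polar_offsets(
    n: int,
    config: BesConfig,
    variant: str,
    rng: np.random.Generator,
) -> BesPolarOffsets:
    """Draw a batch of ``n`` polar offsets.

    ``variant='search'`` uses the circular spiral (sin/cos); ``'swoop'`` the
    hyperbolic one (sinh/cosh). Draw order: the ``n`` angle uniforms first,
    then (in the as_printed dialect and the canonical one alike) the ``n``
    radius uniforms.
    """
    if n < 1:
        raise ValueError("need at least one offset")
    if variant not in ("search", "swoop"):
        raise ValueError("variant must be 'search' or 'swoop'")
    theta = rng.uniform(size=n) * np.pi * config.a_angle
    if config.variant == "canonical":
        radius = theta + config.R_radius * rng.uniform(size=n)
    else:
        radius = rng.uniform(size=n) * config.R_radius * theta
    if variant == "search":
        raw_x = np.sin(theta) * radius
        raw_y = np.cos(theta) * radius
    else:
        raw_x = np.sinh(theta) * radius
        raw_y = np.cosh(theta) * radius
    return BesPolarOffsets(
        theta=theta,
        radius=radius,
        raw_x=raw_x,
        raw_y=raw_y,
        norm_x=_safe_norm(raw_x),
        norm_y=_safe_norm(raw_y),
    )


# --- pure single-step update rules -----------------------------------------
# These take every random draw as an explicit argument so they can be checked
# against straight-line re-implementations on a recorded stream.


def select_candidates(
    positions: np.ndarray,
    best: np.ndarray,
    mean: np.ndarray,
    alpha_ctrl: float,
    r: np.ndarray,
) -> np.ndarray:
    """Select-phase move: P_best + alpha * r_i * (P_mean - P_i)."""
    return best + alpha_ctrl * r[:, None] * (mean - positions)


def search_candidates(
    positions: np.ndarray,
    mean: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
) -> np.ndarray:
    """Search-phase move: P_i + y_i (P_i - P_{i+1}) + x_i (P_i - P_mean).

    The neighbour index is cyclic; a single-agent swarm has a zero neighbour
    term.
    """
    if positions.shape[0] >= 2:
        neighbour = np.roll(positions, -1, axis=0)
        neighbour_term = y[:, None] * (positions - neighbour)
    else:
        logger.debug("single-agent swarm: neighbour term defined as zero")
        neighbour_term = np.zeros_like(positions)
    return positions + neighbour_term + x[:, None] * (positions - mean)


def swoop_candidates(
    positions: np.ndarray,
    best: np.ndarray,
    mean: np.ndarray,
    x1: np.ndarray,
    y1: np.ndarray,
    rand: np.ndarray,
    c1: np.ndarray,
    c2: np.ndarray,
) -> np.ndarray:
    """Swoop-phase move: rand_i P_best + x1_i (P_i - c1_i P_mean) + y1_i (P_i - c2_i P_best)."""
    return (
        rand[:, None] * best
        + x1[:, None] * (positions - c1[:, None] * mean)
        + y1[:, None] * (positions - c2[:, None] * best)
    )


# --- phase operators ---------------------------------------------------------


def bes_select_space(
    swarm: Swarm, config: BesConfig, objective: Objective, rng: np.random.Generator
) -> Swarm:
    """Space-selecting phase (one scalar uniform per agent)."""
    r = rng.uniform(size=len(swarm))
    cand = select_candidates(
        swarm.positions, swarm.best_position, swarm.mean_position, config.alpha_ctrl, r
    )
    cand = swarm.bounds.clip(cand)
    swarm.greedy_accept(cand, evaluate_batch(objective, cand))
    return swarm


def bes_search_space(
    swarm: Swarm, config: BesConfig, objective: Objective, rng: np.random.Generator
) -> Swarm:
    """Space-searching phase with circular-spiral offsets."""
    offsets = bes_polar_offsets(len(swarm), config, "search", rng)
    cand = search_candidates(
        swarm.positions, swarm.mean_position, offsets.norm_x, offsets.norm_y
    )
    cand = swarm.bounds.clip(cand)
    swarm.greedy_accept(cand, evaluate_batch(objective, cand))
    return swarm


def bes_swoop(
    swarm: Swarm, config: BesConfig, objective: Objective, rng: np.random.Generator
) -> Swarm:
    """Swooping phase with hyperbolic-spiral offsets.

    Draw order: offsets (angles, radii), then the rand vector, then c1, then c2.
    """
    offsets = bes_polar_offsets(len(swarm), config, "swoop", rng)
    rand = rng.uniform(size=len(swarm))
    c1 = rng.uniform(1.0, 2.0, size=len(swarm))
    c2 = rng.uniform(1.0, 2.0, size=len(swarm))
    cand = swoop_candidates(
        swarm.positions,
        swarm.best_position,
        swarm.mean_position,
        offsets.norm_x,
        offsets.norm_y,
        rand,
        c1,
        c2,
    )
    cand = swarm.bounds.clip(cand)
    swarm.greedy_accept(cand, evaluate_batch(objective, cand))
    return swarm


def bes_run(
    objective: Objective,
    bounds: Bounds,
    config: BesConfig | None = None,
    rng=None,
) -> OptResult:
    """Full BES run: uniform initialisation, then select -> search -> swoop per iteration.

    Evaluation count is ``pop_size * (1 + 3 * max_iter)``: one evaluation per
    agent at initialisation and one per agent per phase.
    """
    config = config or BesConfig()
    rng = as_rng(rng)
    swarm = Swarm.init_random(objective, bounds, config.pop_size, rng)
    archive = BestSoFar()
    archive.update(swarm)
    archive.record()
    for _ in range(config.max_iter):
        bes_select_space(swarm, config, objective, rng)
        bes_search_space(swarm, config, objective, rng)
        bes_swoop(swarm, config, objective, rng)
        archive.update(swarm)
        archive.record()
    n_evals = config.pop_size * (1 + 3 * config.max_iter)
    result = archive.result(n_evals, optimizer="bes")
    result.final_swarm = swarm  # consumed by the hybrid handoff
    return result
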