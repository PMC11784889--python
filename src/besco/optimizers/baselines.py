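"""Canonical baseline optimizers: Firefly Algorithm and Grey Wolf Optimizer.

Both follow their original formulations (Yang's FFA with full-attractiveness
moves and decaying randomisation; Mirjalili's GWO with the linearly decaying
``a`` coefficient and the alpha/beta/delta average). They share the
:class:`~besco.optimizers._core.OptResult` contract of the other optimizers:
positions are clipped to the box after every move and the reported trace is
the best-so-far fitness, hence non-increasing, with ``best_fitness`` equal to
the objective at ``best_position``.
"""

from __future__ import annotations

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

__all__ = ["FfaConfig", "GwoConfig", "firefly_run", "gwo_run"]


@dataclass(frozen=True)
class FfaConfig:
    """Firefly parameters: base attractiveness beta0, light absorption gamma,
    randomisation weight alpha (decaying geometrically by alpha_decay)."""

    beta0: float = 1.0
    gamma: float = 1.0
    alpha: float = 0.25
    alpha_decay: float = 0.97
    pop_size: int = 50
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.pop_size < 1 or self.max_iter < 0:
            raise ValueError("pop_size must be positive, max_iter non-negative")


@dataclass(frozen=True)
class GwoConfig:
    pop_size: int = 50
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.pop_size < 1 or self.max_iter < 0:
            raise ValueError("pop_size must be positive, max_iter non-negative")


def firefly_run(
    objective: Objective,
    bounds: Bounds,
    config: FfaConfig | None = None,
    rng=None,
) -> OptResult:
    """Firefly Algorithm: each firefly moves toward every brighter one."""
    config = config or FfaConfig()
    rng = as_rng(rng)
    swarm = Swarm.init_random(objective, bounds, config.pop_size, rng)
    archive = BestSoFar()
    archive.update(swarm)
    archive.record()
    scale = bounds.upper - bounds.lower
    alpha = config.alpha
    for _ in range(config.max_iter):
        n = len(swarm)
        # brightness snapshot for the sweep; each attractor j pulls every
        # dimmer firefly toward it (vectorised over the movers)
        brightness = swarm.fitness.copy()
        for j in range(n):
            movers = brightness > brightness[j]
            if not movers.any():
                continue
            diff = swarm.positions[j] - swarm.positions[movers]
            beta = config.beta0 * np.exp(-config.gamma * (diff**2).sum(axis=1))
            step = alpha * (rng.uniform(size=diff.shape) - 0.5) * scale
            swarm.positions[movers] = bounds.clip(
                swarm.positions[movers] + beta[:, None] * diff + step
            )
        swarm.fitness = evaluate_batch(objective, swarm.positions)
        alpha *= config.alpha_decay
        archive.update(swarm)
        archive.record()
    n_evals = config.pop_size * (1 + config.max_iter)
    return archive.result(n_evals, optimizer="ffa")


def gwo_run(
    objective: Objective,
    bounds: Bounds,
    config: GwoConfig | None = None,
    rng=None,
) -> OptResult:
    """Grey Wolf Optimizer with linearly decaying a and alpha/beta/delta leaders."""
    config = config or GwoConfig()
    rng = as_rng(rng)
    swarm = Swarm.init_random(objective, bounds, config.pop_size, rng)
    archive = BestSoFar()
    archive.update(swarm)
    archive.record()
    for it in range(config.max_iter):
        a = 2.0 - 2.0 * it / max(config.max_iter, 1)
        order = np.argsort(swarm.fitness, kind="stable")
        leaders = swarm.positions[order[: min(3, len(swarm))]]
        if leaders.shape[0] < 3:  # tiny swarms reuse the best wolf
            leaders = np.vstack([leaders] * 3)[:3]
        new_positions = np.empty_like(swarm.positions)
        for i in range(len(swarm)):
            estimates = []
            for leader in leaders:
                r1 = rng.uniform(size=bounds.dim)
                r2 = rng.uniform(size=bounds.dim)
                A = 2.0 * a * r1 - a
                C = 2.0 * r2
                D = np.abs(C * leader - swarm.positions[i])
                estimates.append(leader - A * D)
            new_positions[i] = bounds.clip(np.mean(estimates, axis=0))
        swarm.positions = new_positions
        swarm.fitness = evaluate_batch(objective, swarm.positions)
        archive.update(swarm)
        archive.record()
    n_evals = config.pop_size * (1 + config.max_iter)
    return archive.result(n_evals, optimizer="gwo")
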