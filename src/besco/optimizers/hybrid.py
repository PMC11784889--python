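"""Hybrid Bald Eagle Search -> Chimp Optimizer.

BES explores first; its final population is ranked and the best
``carryover`` fraction seeds the CO phase (topped up with fresh uniform
points when the CO population is larger than the carried block). CO then
exploits. The returned best is the better of the two phases and the
concatenated best-so-far trace is globally non-increasing.

A single seeded generator drives both phases, so a run is exactly
reproducible from its seed, and a hybrid with ``chimp.max_iter = 0`` is
bit-for-bit identical to a pure BES run under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core import Bounds, Objective, OptResult, Swarm, as_rng, evaluate_batch
from .bes import BesConfig, bes_run
from .chimp import ChimpConfig, chimp_run

__all__ = ["HybridConfig", "hybrid_bes_co_run"]


@dataclass(frozen=True)
class HybridConfig:
    bes: BesConfig = field(default_factory=BesConfig)
    chimp: ChimpConfig = field(default_factory=ChimpConfig)
    carryover: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.carryover <= 1.0:
            raise ValueError("carryover must lie in (0, 1]")


def hybrid_bes_co_run(
    objective: Objective,
    bounds: Bounds,
    config: HybridConfig | None = None,
    rng=None,
) -> OptResult:
    """Run BES to completion, hand its ranked elite to CO, return the overall best."""
    config = config or HybridConfig()
    rng = as_rng(rng if rng is not None else config.seed)

    bes_result = bes_run(objective, bounds, config.bes, rng)
    bes_swarm: Swarm = bes_result.final_swarm

    n_carry = max(1, int(round(config.carryover * len(bes_swarm))))
    order = np.argsort(bes_swarm.fitness, kind="stable")[:n_carry]
    seed_positions = bes_swarm.positions[order]
    seed_fitness = bes_swarm.fitness[order]

    n_extra_evals = 0
    target_pop = config.chimp.pop_size
    if seed_positions.shape[0] < target_pop:
        extra = bounds.sample(rng, target_pop - seed_positions.shape[0])
        extra_fit = evaluate_batch(objective, extra)
        n_extra_evals = extra.shape[0]
        seed_positions = np.vstack([seed_positions, extra])
        seed_fitness = np.concatenate([seed_fitness, extra_fit])

    co_result = chimp_run(
        objective,
        bounds,
        config.chimp,
        rng,
        initial_population=seed_positions,
        initial_fitness=seed_fitness,
    )

    # CO's trace starts at the carried-over best; drop that duplicate entry and
    # enforce the global best-so-far accumulation across the seam.
    trace = np.concatenate([bes_result.trace, co_result.trace[1:]])
    trace = np.minimum.accumulate(trace)

    if co_result.best_fitness < bes_result.best_fitness:
        best_position, best_fitness = co_result.best_position, co_result.best_fitness
    else:
        best_position, best_fitness = bes_result.best_position, bes_result.best_fitness

    result = OptResult(
        best_position=best_position,
        best_fitness=float(best_fitness),
        trace=trace,
        n_evaluations=bes_result.n_evaluations + n_extra_evals + co_result.n_evaluations,
        optimizer="bes-co",
    )
    result.final_swarm = co_result.final_swarm
    return result
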