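"""Bounded continuous black-box optimizers: BES, CO, hybrid BES-CO, FFA, GWO."""

from ._core import Agent, BestSoFar, Bounds, OptResult, Swarm, evaluate_batch
from .baselines import FfaConfig, GwoConfig, firefly_run, gwo_run
from .bes import (
    BesConfig,
    BesPolarOffsets,
    bes_polar_offsets,
    bes_run,
    bes_search_space,
    bes_select_space,
    bes_swoop,
)
from .chimp import (
    ChimpConfig,
    GroupAssignment,
    chimp_exploit,
    chimp_form_groups,
    chimp_hunt,
    chimp_run,
)
from .hybrid import HybridConfig, hybrid_bes_co_run

__all__ = [
    "Agent",
    "BestSoFar",
    "Bounds",
    "OptResult",
    "Swarm",
    "evaluate_batch",
    "BesConfig",
    "BesPolarOffsets",
    "bes_polar_offsets",
    "bes_run",
    "bes_select_space",
    "bes_search_space",
    "bes_swoop",
    "ChimpConfig",
    "GroupAssignment",
    "chimp_form_groups",
    "chimp_hunt",
    "chimp_exploit",
    "chimp_run",
    "HybridConfig",
    "hybrid_bes_co_run",
    "FfaConfig",
    "GwoConfig",
    "firefly_run",
    "gwo_run",
    "run_optimizer",
]


_RUNNERS = {
    "bes": ("bes", bes_run, BesConfig),
    "chimp": ("chimp", chimp_run, ChimpConfig),
    "co": ("chimp", chimp_run, ChimpConfig),
    "bes-co": ("bes-co", hybrid_bes_co_run, HybridConfig),
    "ffa": ("ffa", firefly_run, FfaConfig),
    "gwo": ("gwo", gwo_run, GwoConfig),
}


def run_optimizer(name, objective, bounds, config=None, rng=None) -> OptResult:
    """Dispatch an optimizer by name ('bes', 'chimp', 'bes-co', 'ffa', 'gwo')."""
    try:
        _, runner, config_cls = _RUNNERS[name]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_RUNNERS)}"
        ) from None
    if config is None:
        config = config_cls()
    return runner(objective, bounds, config, rng)
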