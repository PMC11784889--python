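import numpy as np
import pytest

from besco import Bounds, benchmark_objective, gen_cohort


@pytest.fixture
def box3() -> Bounds:
    return Bounds(np.full(3, -5.0), np.full(3, 5.0))


@pytest.fixture
def sphere3():
    return benchmark_objective("sphere", 3)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort for SVR-level tests (kept small for speed)."""
    return gen_cohort(n=120, seed=11)


class ConstantRNG:
    """Stand-in generator returning a fixed value from every uniform draw."""

    def __init__(self, value: float = 0.0):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@pytest.fixture
def zero_rng():
    return ConstantRNG(0.0)
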