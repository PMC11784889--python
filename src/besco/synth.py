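"""Seedable generators: synthetic patient cohorts, planted-outlier fixtures,
and analytic benchmark objectives for optimizer validation.

The cohort generator emulates the qualitative structure of a sarcoidosis
biomarker table: serum ACE (U/mL, right-skewed around its <=68 reference
range) drives serum sIL-2R (pg/mL) through a saturating monotone link,
disease status adds a positive sIL-2R shift (so sIL-2R discriminates the
diagnosis), and sex is drawn independently of everything else (so it does
not). Noise is multiplicative log-normal, keeping sIL-2R positive and making
its spread grow with its mean; ``noise_sd = 0`` gives an exactly
deterministic table. Every generator is a pure function of its parameters
and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortGenParams",
    "gen_cohort",
    "gen_outlier_fixture",
    "BenchmarkObjective",
    "benchmark_objective",
]


@dataclass(frozen=True)
class CohortGenParams:
    """Generative settings for a synthetic cohort.

    n                  : cohort size (default 200, a realistic desk-scale study).
    sex_balance        : fraction of rows with sex = 1.
    disease_prevalence : fraction of rows with diagnosis = 1.
    ace_location       : log-scale median of ACE in U/mL (median ~ 45 keeps the
                         bulk under the 68 U/mL reference with a right tail above).
    ace_scale          : log-normal sigma of ACE.
    ace_tail_clip      : truncation of the log-normal at +/- this many sigma,
                         emulating the finite dynamic range of the kinetic
                         assay; keeps single extreme values from dominating.
    sil2r_base         : sIL-2R floor in pg/mL.
    sil2r_amplitude    : span of the saturating ACE -> sIL-2R link, pg/mL.
    ace_halfsat        : ACE value (U/mL) at which the link reaches half span.
    ace_hill           : Hill exponent of the link; the default gives a
                         switch-like rise near the upper-reference ACE range
                         (threshold-type dose response).
    disease_shift      : additive sIL-2R shift for diagnosed rows, pg/mL; the
                         default makes sIL-2R clearly discriminative of the
                         diagnosis while leaving most variance ACE-driven.
    noise_sd           : sigma of the multiplicative log-normal noise on sIL-2R.
    seed               : RNG seed.
    """

    n: int = 200
    sex_balance: float = 0.5
    disease_prevalence: float = 0.5
    ace_location: float = 45.0
    ace_scale: float = 0.45
    ace_tail_clip: float = 2.0
    sil2r_base: float = 800.0
    sil2r_amplitude: float = 5000.0
    ace_halfsat: float = 60.0
    ace_hill: float = 25.0
    disease_shift: float = 1000.0
    noise_sd: float = 0.06
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be at least 4")
        for name in ("sex_balance", "disease_prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.ace_location, self.ace_scale, self.sil2r_base,
               self.sil2r_amplitude, self.ace_halfsat, self.ace_tail_clip,
               self.ace_hill) <= 0:
            raise ValueError("scale/location parameters must be positive")
        if self.disease_shift < 0:
            raise ValueError("disease_shift must be non-negative")


def sil2r_link(ace: np.ndarray, diagnosis: np.ndarray, params: CohortGenParams) -> np.ndarray:
    """Expected sIL-2R: base + amplitude * Hill(ACE) + shift * diagnosis.

    Hill(ACE) = ACE^h / (ACE^h + K^h), evaluated as a logistic in log(ACE)
    for numerical stability at large Hill exponents.
    """
    ace = np.asarray(ace, dtype=float)
    from scipy.special import expit

    saturating = expit(params.ace_hill * (np.log(ace) - np.log(params.ace_halfsat)))
    return (
        params.sil2r_base
        + params.sil2r_amplitude * saturating
        + params.disease_shift * np.asarray(diagnosis, dtype=float)
    )


def gen_cohort(params: CohortGenParams | None = None, **overrides) -> pd.DataFrame:
    """Generate a synthetic cohort table with columns sex, ACE, sIL2R, diagnosis.

    Keyword overrides are applied on top of ``params`` (or the defaults), e.g.
    ``gen_cohort(n=50, noise_sd=0.0, seed=1)``.
    """
    params = replace(params or CohortGenParams(), **overrides)
    rng = np.random.default_rng(params.seed)
    sex = (rng.uniform(size=params.n) < params.sex_balance).astype(int)
    diagnosis = (rng.uniform(size=params.n) < params.disease_prevalence).astype(int)
    z = np.clip(
        rng.standard_normal(params.n), -params.ace_tail_clip, params.ace_tail_clip
    )
    ace = params.ace_location * np.exp(params.ace_scale * z)
    mean_sil2r = sil2r_link(ace, diagnosis, params)
    if params.noise_sd > 0:
        # mean-preserving log-normal: E[m * exp(s Z - s^2/2)] = m
        noise = np.exp(
            params.noise_sd * rng.standard_normal(params.n) - 0.5 * params.noise_sd**2
        )
    else:
        noise = 1.0
    sil2r = mean_sil2r * noise
    return pd.DataFrame(
        {"sex": sex, "ACE": ace, "sIL2R": sil2r, "diagnosis": diagnosis}
    )


def gen_outlier_fixture(
    n: int = 100,
    n_planted: int = 3,
    magnitude: float = 50.0,
    seed: int | None = None,
    column: str = "sIL2R",
) -> tuple[pd.DataFrame, np.ndarray]:
    """A clean cohort with ``n_planted`` values in ``column`` blown up to extremes.

    The baseline is built to sit strictly inside both detectors' fences:
    ACE is uniform on a plausible clinical span and sIL-2R rises linearly
    with ACE, noiselessly — both columns are then uniform, hence bounded and
    light-tailed, and neither the z-score nor the IQR rule can fire on the
    clean table (a mixture shift by diagnosis would leave a sparse upper
    tail that the IQR fence occasionally clips, so the fixture omits it). Every plant — ``magnitude`` times the column median — then
    lands far outside the fences. Returns the table and the sorted planted
    row indices (ground truth).
    """
    if n_planted >= n:
        raise ValueError("n_planted must be smaller than n")
    if n_planted < 0:
        raise ValueError("n_planted must be non-negative")
    rng = np.random.default_rng(seed)
    sex = (rng.uniform(size=n) < 0.5).astype(int)
    diagnosis = (rng.uniform(size=n) < 0.5).astype(int)
    ace = rng.uniform(25.0, 85.0, size=n)
    sil2r = 1500.0 + 35.0 * ace
    table = pd.DataFrame({"sex": sex, "ACE": ace, "sIL2R": sil2r, "diagnosis": diagnosis})
    planted = np.sort(rng.choice(n, size=n_planted, replace=False))
    if n_planted:
        median = float(table[column].median())
        table.loc[planted, column] = magnitude * median * rng.uniform(
            0.9, 1.1, size=n_planted
        )
        if magnitude < 5.0:
            warnings.warn(
                "planted magnitude below 5x the median may not exceed detector fences",
                stacklevel=2,
            )
    return table, planted


@dataclass(frozen=True)
class BenchmarkObjective:
    """An analytic test function with known optimum, callable on points or batches."""

    name: str
    dimension: int
    optimum_position: np.ndarray
    optimum_value: float
    batched: bool = True  # the optimizer engine may pass an (n, d) matrix

    def __call__(self, x: np.ndarray) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.dimension:
            raise ValueError(f"{self.name} expects dimension {self.dimension}")
        out = _FORMULAS[self.name](x)
        return float(out[0]) if single else out


def _sphere(x: np.ndarray) -> np.ndarray:
    return (x**2).sum(axis=1)


def _rosenbrock(x: np.ndarray) -> np.ndarray:
    return (100.0 * (x[:, 1:] - x[:, :-1] ** 2) ** 2 + (1.0 - x[:, :-1]) ** 2).sum(axis=1)


def _rastrigin(x: np.ndarray) -> np.ndarray:
    return 10.0 * x.shape[1] + (x**2 - 10.0 * np.cos(2.0 * np.pi * x)).sum(axis=1)


_FORMULAS = {"sphere": _sphere, "rosenbrock": _rosenbrock, "rastrigin": _rastrigin}


def benchmark_objective(name: str, dimension: int = 3) -> BenchmarkObjective:
    """Build a named benchmark objective ('sphere', 'rosenbrock', 'rastrigin')."""
    if name not in _FORMULAS:
        raise ValueError(f"unknown benchmark {name!r}; choose from {sorted(_FORMULAS)}")
    if dimension < 1:
        raise ValueError("dimension must be positive")
    if name == "rosenbrock":
        if dimension < 2:
            raise ValueError("rosenbrock needs dimension >= 2")
        opt = np.ones(dimension)
    else:
        opt = np.zeros(dimension)
    return BenchmarkObjective(
        name=name, dimension=dimension, optimum_position=opt, optimum_value=0.0
    )
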