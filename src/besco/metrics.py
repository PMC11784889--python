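"""Regression evaluation metrics and the replicate two-sample t-test protocol.

Three flavours of "R squared" circulate in the applied literature and they
disagree off the diagonal, so all three are explicit here:

``printed``
    the Pearson correlation of actual and predicted (unsquared);
``squared_pearson``
    its square — invariant to affine miscalibration of the predictions;
``coefficient_of_determination``
    1 - SSE/SST, which *does* punish bias and rescaling.

All three equal 1 exactly when predicted == actual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "rmse",
    "mae",
    "mape",
    "r_squared",
    "compare_ttest",
    "TTestResult",
    "replicate_runs",
]


def _pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.ndim != 1 or a.shape != p.shape:
        raise ValueError("actual and predicted must be 1-D vectors of equal length")
    if a.size == 0:
        raise ValueError("empty prediction pair")
    if not (np.isfinite(a).all() and np.isfinite(p).all()):
        raise ValueError("prediction pair must be finite")
    return a, p


def rmse(actual, predicted) -> float:
    """Root-mean-square error, sqrt(mean((a - p)^2))."""
    a, p = _pair(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def mae(actual, predicted) -> float:
    """Mean absolute error."""
    a, p = _pair(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def mape(actual, predicted, zero_guard: bool = True) -> float:
    """Mean absolute percentage error, in percent.

    Rows with actual = 0 are excluded when ``zero_guard`` is on (the excluded
    count is logged); with the guard off they raise.
    """
    a, p = _pair(actual, predicted)
    zeros = a == 0.0
    if zeros.any():
        if not zero_guard:
            raise ValueError("MAPE undefined: zero actual values present")
        logger.info("mape: excluding %d rows with zero actual value", int(zeros.sum()))
        a, p = a[~zeros], p[~zeros]
        if a.size == 0:
            raise ValueError("MAPE undefined: all actual values are zero")
    return float(100.0 * np.mean(np.abs((a - p) / a)))


def r_squared(actual, predicted, variant: str = "squared_pearson") -> float:
    """Goodness-of-fit under one of the three conventions (see module docstring)."""
    a, p = _pair(actual, predicted)
    if a.size < 2:
        raise ValueError("r_squared needs at least 2 points")
    if variant == "coefficient_of_determination":
        sst = float(np.sum((a - a.mean()) ** 2))
        if sst == 0.0:
            raise ValueError("zero variance in actual values")
        sse = float(np.sum((a - p) ** 2))
        return 1.0 - sse / sst
    if variant in ("printed", "squared_pearson"):
        da, dp = a - a.mean(), p - p.mean()
        denom = np.sqrt(np.sum(da**2) * np.sum(dp**2))
        if denom == 0.0:
            raise ValueError("zero variance: correlation undefined")
        r = float(np.sum(da * dp) / denom)
        return r if variant == "printed" else r * r
    raise ValueError(
        "variant must be 'printed', 'squared_pearson' or 'coefficient_of_determination'"
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    reject: bool


def compare_ttest(runs_a, runs_b, kind: str = "pooled", alpha: float = 0.05) -> TTestResult:
    """Two-sided two-sample t-test on replicate scores.

    ``kind='pooled'`` is the classic equal-variance Student test,
    ``'welch'`` drops the equal-variance assumption. The null is rejected
    iff p < alpha.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each run vector needs at least 2 entries")
    if kind not in ("pooled", "welch"):
        raise ValueError("kind must be 'pooled' or 'welch'")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, reject=False)
        if kind == "pooled":
            raise ValueError("degenerate pooled t-test: both samples have zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=(kind == "pooled"))
    return TTestResult(t=float(t), p=float(p), reject=bool(p < alpha))


def replicate_runs(
    tuners: dict,
    dataset: pd.DataFrame,
    R: int = 10,
    seed_base: int = 0,
) -> pd.DataFrame:
    """Run each tuning pipeline R times with seeds ``seed_base .. seed_base+R-1``.

    ``tuners`` maps a model name to a callable ``f(dataset, seed) -> rmse``
    (the comparison harness in :mod:`besco.compare` provides these). Returns a
    DataFrame of per-run held-out RMSE with one column per model and one row
    per seed — the run matrix fed to :func:`compare_ttest`.
    """
    if R < 2:
        raise ValueError("R must be at least 2")
    seeds = [seed_base + r for r in range(R)]
    data = {
        name: [float(run(dataset, seed)) for seed in seeds]
        for name, run in tuners.items()
    }
    return pd.DataFrame(data, index=pd.Index(seeds, name="seed"))
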