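"""Epsilon-SVR fitting, the cross-validated RMSE fitness, and the
metaheuristic tuning loop.

The regressor is the standard epsilon-insensitive support vector machine with
an RBF kernel: predictions are f(x) = sum_j a_j K(x_j, x) + b, residuals
inside the epsilon tube cost nothing, and residuals beyond it are penalised
linearly (loss exponent p = 1, solved by libsvm via scikit-learn) or
quadratically (p = 2, solved here by L-BFGS on the kernelised primal).

Tuning searches the (C, epsilon, gamma) box with any of the package's swarm
optimizers, scoring each candidate by its mean validation-fold RMSE. Features
and target are standardized inside each training fold only, so the fitness —
and every RMSE this module reports — is in standardized target units.

The model-object surface mirrors the statsmodels idiom: build an
:class:`SVRTuner` from data (or :meth:`SVRTuner.from_dataframe`), call
``fit()`` to run the optimizer, and read estimates, diagnostics and
``summary()`` off the returned :class:`SVRTuningResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import KFold, train_test_split
from sklearn.svm import SVR as _SklearnSVR

from .metrics import r_squared, rmse
from .optimizers import (
    BesConfig,
    Bounds,
    ChimpConfig,
    FfaConfig,
    GwoConfig,
    HybridConfig,
    OptResult,
    run_optimizer,
)

__all__ = [
    "SvrHyperparams",
    "HyperparamSpace",
    "SvrFitConfig",
    "SvrModel",
    "EvalProtocol",
    "TunedResult",
    "svr_fit",
    "svr_predict",
    "hyperparam_fitness",
    "tune_svr",
    "budget_config",
    "SVRTuner",
    "SVRTuningResults",
]


@dataclass(frozen=True)
class SvrHyperparams:
    """The tuned point: penalty C, tube half-width epsilon, RBF width gamma."""

    C: float
    eps_tube: float
    gamma_kernel: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma_kernel <= 0:
            raise ValueError("C and gamma_kernel must be positive")
        if self.eps_tube < 0:
            raise ValueError("eps_tube must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array([self.C, self.eps_tube, self.gamma_kernel])


@dataclass(frozen=True)
class HyperparamSpace:
    """The hard search box for (C, epsilon, gamma)."""

    c_range: tuple[float, float] = (1000.0, 10000.0)
    eps_range: tuple[float, float] = (0.001, 1.0)
    gamma_range: tuple[float, float] = (1.0, 20.0)

    def __post_init__(self) -> None:
        for name in ("c_range", "eps_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lower < upper")

    def to_bounds(self, log_c: bool = False) -> Bounds:
        c_lo, c_hi = self.c_range
        if log_c:
            c_lo, c_hi = np.log10(c_lo), np.log10(c_hi)
        return Bounds(
            lower=np.array([c_lo, self.eps_range[0], self.gamma_range[0]]),
            upper=np.array([c_hi, self.eps_range[1], self.gamma_range[1]]),
        )

    def point_to_params(self, point: np.ndarray, log_c: bool = False) -> SvrHyperparams:
        c = 10.0 ** point[0] if log_c else point[0]
        return SvrHyperparams(C=float(c), eps_tube=float(point[1]), gamma_kernel=float(point[2]))

    def contains(self, params: SvrHyperparams) -> bool:
        return (
            self.c_range[0] <= params.C <= self.c_range[1]
            and self.eps_range[0] <= params.eps_tube <= self.eps_range[1]
            and self.gamma_range[0] <= params.gamma_kernel <= self.gamma_range[1]
        )


@dataclass(frozen=True)
class SvrFitConfig:
    """Solver settings: loss exponent p in {1, 2}, tolerance, iteration cap."""

    loss_exponent: int = 1
    tol: float = 1e-3
    max_iter: int = 2_000

    def __post_init__(self) -> None:
        if self.loss_exponent not in (1, 2):
            raise ValueError("loss_exponent must be 1 or 2")


@dataclass
class SvrModel:
    """A fitted epsilon-SVR in dual form.

    ``dual_coef @ K(support_vectors, x) + bias`` is the prediction; the slack
    summary records the training residuals beyond the epsilon tube.
    """

    bias: float
    dual_coef: np.ndarray
    support_vectors: np.ndarray
    params: SvrHyperparams
    fit_config: SvrFitConfig
    n_features: int
    slack_max: float = 0.0
    slack_mean: float = 0.0

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"X must have {self.n_features} columns")
        if self.n_support == 0:  # every training point inside the tube
            return np.full(X.shape[0], self.bias)
        K = rbf_kernel(X, self.support_vectors, gamma=self.params.gamma_kernel)
        return K @ self.dual_coef + self.bias


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    if y.shape != (X.shape[0],) or X.shape[0] < 1:
        raise ValueError("y must be one target per row of X")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    return X, y


def _fit_squared_loss(X, y, params, config) -> tuple[np.ndarray, float]:
    """Kernelised primal with squared epsilon-insensitive loss, via L-BFGS.

    Objective over (a, b): 0.5 a'Ka + C sum max(0, |y - Ka - b| - eps)^2.
    The loss is continuously differentiable, so a quasi-Newton solve on the
    representer-theorem parametrisation is exact enough at tol.
    """
    n = X.shape[0]
    K = rbf_kernel(X, gamma=params.gamma_kernel)

    def objective(z):
        a, b = z[:n], z[n]
        f = K @ a + b
        r = y - f
        s = np.sign(r) * np.maximum(0.0, np.abs(r) - params.eps_tube)
        value = 0.5 * a @ (K @ a) + params.C * (s @ s)
        grad_a = K @ (a - 2.0 * params.C * s)
        grad_b = -2.0 * params.C * s.sum()
        return value, np.concatenate([grad_a, [grad_b]])

    z0 = np.zeros(n + 1)
    z0[n] = y.mean()
    res = minimize(
        objective,
        z0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": config.tol * 1e-6, "gtol": config.tol * 1e-3},
    )
    return res.x[:n], float(res.x[n])


def svr_fit(X, y, params: SvrHyperparams, fit_config: SvrFitConfig | None = None) -> SvrModel:
    """Fit an epsilon-insensitive RBF regressor; deterministic for fixed inputs."""
    fit_config = fit_config or SvrFitConfig()
    X, y = _validate_xy(X, y)
    if fit_config.loss_exponent == 1:
        est = _SklearnSVR(
            kernel="rbf",
            C=params.C,
            epsilon=params.eps_tube,
            gamma=params.gamma_kernel,
            tol=fit_config.tol,
            max_iter=fit_config.max_iter,
        )
        with warnings.catch_warnings():
            # the iteration cap is a deliberate budget for extreme candidate
            # hyperparameters; truncated solves are still deterministic
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
        dual_coef = est.dual_coef_.ravel().copy()
        support = est.support_vectors_.copy()
        bias = float(est.intercept_[0])
    else:
        dual_coef, bias = _fit_squared_loss(X, y, params, fit_config)
        support = X.copy()
    model = SvrModel(
        bias=bias,
        dual_coef=dual_coef,
        support_vectors=support,
        params=params,
        fit_config=fit_config,
        n_features=X.shape[1],
    )
    slack = np.maximum(0.0, np.abs(y - model.predict(X)) - params.eps_tube)
    model.slack_max = float(slack.max(initial=0.0))
    model.slack_mean = float(slack.mean()) if slack.size else 0.0
    return model


def svr_predict(model: SvrModel, X) -> np.ndarray:
    """Evaluate the fitted regressor row-wise; see :meth:`SvrModel.predict`."""
    return model.predict(X)


@dataclass(frozen=True)
class EvalProtocol:
    """How candidate hyperparameters are scored: seeded k-fold CV or holdout."""

    scheme: str = "kfold"
    k: int = 5
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("kfold", "holdout"):
            raise ValueError("scheme must be 'kfold' or 'holdout'")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("k must be at least 2")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")

    def splits(self, n: int):
        """Yield (train_idx, val_idx) pairs; identical seed => identical folds."""
        idx = np.arange(n)
        if self.scheme == "kfold":
            if n < self.k:
                raise ValueError("fewer rows than folds")
            kf = KFold(n_splits=self.k, shuffle=True, random_state=self.seed)
            yield from kf.split(idx)
        else:
            train, val = train_test_split(
                idx, test_size=self.holdout_fraction, random_state=self.seed
            )
            if len(val) < 1 or len(train) < 1:
                raise ValueError("holdout split produced an empty part")
            yield train, val


class _FoldScaler:
    """Per-fold standardization of features and (optionally) the target."""

    def __init__(self, X_train, y_train, standardize=True, scale_target=True):
        if standardize:
            self.x_mean = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            self.x_sd = np.where(sd > 0, sd, 1.0)
        else:
            self.x_mean, self.x_sd = 0.0, 1.0
        if scale_target:
            self.y_mean = y_train.mean()
            sd = y_train.std()
            self.y_sd = sd if sd > 0 else 1.0
        else:
            self.y_mean, self.y_sd = 0.0, 1.0

    def x(self, X):
        return (X - self.x_mean) / self.x_sd

    def y(self, y):
        return (y - self.y_mean) / self.y_sd

    def y_inverse(self, y_scaled):
        return y_scaled * self.y_sd + self.y_mean


def hyperparam_fitness(
    X,
    y,
    protocol: EvalProtocol,
    params: SvrHyperparams,
    fit_config: SvrFitConfig | None = None,
    standardize: bool = True,
    scale_target: bool = True,
) -> float:
    """Mean validation-fold RMSE of the SVR at ``params`` (standardized units).

    Scaling statistics come from each training fold only, so no validation
    information leaks into the fit. Deterministic given the protocol seed.
    """
    X, y = _validate_xy(X, y)
    fold_scores = []
    for train_idx, val_idx in protocol.splits(X.shape[0]):
        scaler = _FoldScaler(X[train_idx], y[train_idx], standardize, scale_target)
        model = svr_fit(scaler.x(X[train_idx]), scaler.y(y[train_idx]), params, fit_config)
        pred = model.predict(scaler.x(X[val_idx]))
        fold_scores.append(rmse(scaler.y(y[val_idx]), pred))
    return float(np.mean(fold_scores))


@dataclass
class TunedResult:
    """Outcome of a tuning run: the best point, its CV RMSE, and the trace."""

    best_params: SvrHyperparams
    best_fitness: float
    trace: np.ndarray
    optimizer: str
    n_evaluations: int
    seed: int | None
    model: "FittedPipeline"
    space: HyperparamSpace

    def to_flat_dict(self) -> dict:
        """Key-value form for the results text file."""
        return {
            "optimizer": self.optimizer,
            "C": self.best_params.C,
            "eps_tube": self.best_params.eps_tube,
            "gamma_kernel": self.best_params.gamma_kernel,
            "cv_rmse": self.best_fitness,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
        }


@dataclass
class FittedPipeline:
    """Final refit on all rows: the fold-style scaler plus the SVR, predicting
    in original target units."""

    scaler: _FoldScaler
    model: SvrModel

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.scaler.y_inverse(self.model.predict(self.scaler.x(X)))

    def predict_scaled(self, X) -> np.ndarray:
        return self.model.predict(self.scaler.x(np.asarray(X, dtype=float)))

    def score_scaled(self, X, y) -> tuple[float, float]:
        """(RMSE, R^2 coefficient-of-determination) in standardized target units."""
        y_scaled = self.scaler.y(np.asarray(y, dtype=float))
        pred = self.predict_scaled(X)
        return rmse(y_scaled, pred), r_squared(y_scaled, pred, "coefficient_of_determination")


def fit_pipeline(
    X,
    y,
    params: SvrHyperparams,
    fit_config: SvrFitConfig | None = None,
    standardize: bool = True,
    scale_target: bool = True,
) -> FittedPipeline:
    """Standardize on all rows and fit the SVR at fixed hyperparameters."""
    X, y = _validate_xy(X, y)
    scaler = _FoldScaler(X, y, standardize, scale_target)
    model = svr_fit(scaler.x(X), scaler.y(y), params, fit_config)
    return FittedPipeline(scaler=scaler, model=model)


def budget_config(
    optimizer: str, pop_size: int = 50, max_iter: int = 100, seed: int | None = None
):
    """Build an optimizer config of the requested budget for any optimizer name.

    For the hybrid, ``max_iter`` applies to each phase.
    """
    if optimizer == "bes":
        return BesConfig(pop_size=pop_size, max_iter=max_iter)
    if optimizer in ("chimp", "co"):
        return ChimpConfig(pop_size=pop_size, max_iter=max_iter)
    if optimizer == "bes-co":
        return HybridConfig(
            bes=BesConfig(pop_size=pop_size, max_iter=max_iter),
            chimp=ChimpConfig(pop_size=pop_size, max_iter=max_iter),
            seed=seed,
        )
    if optimizer == "ffa":
        return FfaConfig(pop_size=pop_size, max_iter=max_iter)
    if optimizer == "gwo":
        return GwoConfig(pop_size=pop_size, max_iter=max_iter)
    raise ValueError(f"unknown optimizer {optimizer!r}")


def tune_svr(
    X,
    y,
    space: HyperparamSpace | None = None,
    optimizer: str = "bes-co",
    optimizer_config=None,
    protocol: EvalProtocol | None = None,
    seed: int | None = None,
    fit_config: SvrFitConfig | None = None,
    standardize: bool = True,
    scale_target: bool = True,
    log_c: bool = False,
) -> TunedResult:
    """Search the (C, epsilon, gamma) box with a swarm optimizer.

    The objective handed to the optimizer is :func:`hyperparam_fitness` at a
    fixed, seeded protocol, so the fitness landscape is deterministic within a
    run. The winning point is refit on all rows.
    """
    space = space or HyperparamSpace()
    protocol = protocol or EvalProtocol(seed=0 if seed is None else seed)
    X, y = _validate_xy(X, y)

    def objective(point: np.ndarray) -> float:
        params = space.point_to_params(point, log_c=log_c)
        return hyperparam_fitness(
            X, y, protocol, params, fit_config, standardize, scale_target
        )

    bounds = space.to_bounds(log_c=log_c)
    rng = np.random.default_rng(seed)
    result: OptResult = run_optimizer(optimizer, objective, bounds, optimizer_config, rng)

    best_params = space.point_to_params(result.best_position, log_c=log_c)
    pipeline = fit_pipeline(X, y, best_params, fit_config, standardize, scale_target)
    return TunedResult(
        best_params=best_params,
        best_fitness=result.best_fitness,
        trace=result.trace,
        optimizer=result.optimizer,
        n_evaluations=result.n_evaluations,
        seed=seed,
        model=pipeline,
        space=space,
    )


class SVRTuner:
    """Model object: an epsilon-SVR whose hyperparameters are to be tuned on data.

    Parameters
    ----------
    X, y : training features and target.
    space : the (C, epsilon, gamma) search box.
    protocol : how candidates are scored (default seeded 5-fold CV).
    fit_config : SVR solver settings.
    standardize, scale_target : per-fold z-scaling toggles (default on; the
        RBF kernel is scale-sensitive and the biomarkers span orders of
        magnitude).
    """

    def __init__(
        self,
        X,
        y,
        space: HyperparamSpace | None = None,
        protocol: EvalProtocol | None = None,
        fit_config: SvrFitConfig | None = None,
        standardize: bool = True,
        scale_target: bool = True,
        log_c: bool = False,
        feature_names: Sequence[str] | None = None,
        target_name: str = "y",
    ):
        self.X, self.y = _validate_xy(X, y)
        self.space = space or HyperparamSpace()
        self.protocol = protocol
        self.fit_config = fit_config or SvrFitConfig()
        self.standardize = standardize
        self.scale_target = scale_target
        self.log_c = log_c
        self.feature_names = list(
            feature_names or [f"x{j}" for j in range(self.X.shape[1])]
        )
        self.target_name = target_name

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        features: Sequence[str] = ("ACE", "sex"),
        target: str = "sIL2R",
        **kwargs,
    ) -> "SVRTuner":
        missing = [c for c in (*features, target) if c not in df.columns]
        if missing:
            raise ValueError(f"dataframe is missing column(s): {', '.join(missing)}")
        return cls(
            df.loc[:, list(features)].to_numpy(dtype=float),
            df[target].to_numpy(dtype=float),
            feature_names=list(features),
            target_name=target,
            **kwargs,
        )

    def fit(
        self,
        optimizer: str = "bes-co",
        config=None,
        seed: int | None = None,
        pop_size: int | None = None,
        max_iter: int | None = None,
    ) -> "SVRTuningResults":
        """Run the tuning loop and return the results object.

        ``pop_size``/``max_iter`` are a convenience for building a config of
        the right class when none is supplied.
        """
        if config is None and (pop_size is not None or max_iter is not None):
            config = budget_config(
                optimizer, pop_size=pop_size or 50, max_iter=max_iter or 100
            )
        protocol = self.protocol or EvalProtocol(seed=0 if seed is None else seed)
        tuned = tune_svr(
            self.X,
            self.y,
            space=self.space,
            optimizer=optimizer,
            optimizer_config=config,
            protocol=protocol,
            seed=seed,
            fit_config=self.fit_config,
            standardize=self.standardize,
            scale_target=self.scale_target,
            log_c=self.log_c,
        )
        return SVRTuningResults(self, tuned)


class SVRTuningResults:
    """Results of one tuning run, statsmodels-style.

    Exposes the tuned hyperparameters, the cross-validated RMSE (standardized
    target units), the convergence trace, training-fit diagnostics, and a
    text ``summary()``.
    """

    def __init__(self, tuner: SVRTuner, tuned: TunedResult):
        self.model = tuner
        self._tuned = tuned

    # -- estimates -----------------------------------------------------------
    @property
    def best_params(self) -> SvrHyperparams:
        return self._tuned.best_params

    @property
    def cv_rmse(self) -> float:
        return self._tuned.best_fitness

    @property
    def trace(self) -> np.ndarray:
        return self._tuned.trace

    @property
    def n_evaluations(self) -> int:
        return self._tuned.n_evaluations

    @property
    def optimizer(self) -> str:
        return self._tuned.optimizer

    @property
    def pipeline(self) -> FittedPipeline:
        return self._tuned.model

    def predict(self, X) -> np.ndarray:
        """Predict the target in original units."""
        return self.pipeline.predict(X)

    def training_scores(self) -> dict[str, float]:
        """RMSE / R^2 of the final refit on its own training rows (scaled units)."""
        r, r2 = self.pipeline.score_scaled(self.model.X, self.model.y)
        return {"train_rmse": r, "train_r2": r2}

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.trace.size),
                "best_fitness": self.trace,
            }
        )

    def plot_convergence(self, ax=None):
        """Best-so-far CV RMSE per iteration (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(self.trace.size), self.trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best CV RMSE (standardized)")
        ax.set_title(f"{self.optimizer} convergence")
        return ax

    def summary(self) -> str:
        p = self.best_params
        train = self.training_scores()
        lines = [
            "              SVR hyperparameter tuning results",
            "=" * 64,
            f"Optimizer:          {self.optimizer}",
            f"Objective:          mean CV RMSE ({'kfold' if self.model.protocol is None else self.model.protocol.scheme}, standardized target)",
            f"Target:             {self.model.target_name}",
            f"Features:           {', '.join(self.model.feature_names)}",
            f"N observations:     {self.model.X.shape[0]}",
            f"N evaluations:      {self.n_evaluations}",
            "-" * 64,
            f"C (penalty):        {p.C:.4g}",
            f"epsilon (tube):     {p.eps_tube:.4g}",
            f"gamma (RBF width):  {p.gamma_kernel:.4g}",
            "-" * 64,
            f"CV RMSE:            {self.cv_rmse:.4f}",
            f"Train RMSE:         {train['train_rmse']:.4f}",
            f"Train R^2:          {train['train_r2']:.4f}",
            f"Support vectors:    {self.pipeline.model.n_support}",
            "=" * 64,
        ]
        return "\n".join(lines)
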