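"""Multi-model comparison harness.

Runs every requested model — default-hyperparameter SVR, metaheuristic-tuned
SVRs (BES, CO, hybrid BES-CO, FFA, GWO), decision tree and random forest —
under one shared protocol and seed schedule: per replicate seed the cohort is
split into train/test, models are tuned/fitted on the training part only, and
scored on the held-out part in standardized target units. The per-run RMSE
matrix feeds pairwise two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeRegressor

from .metrics import compare_ttest, r_squared, rmse
from .svr import (
    EvalProtocol,
    SvrHyperparams,
    _FoldScaler,
    budget_config,
    fit_pipeline,
    tune_svr,
)

__all__ = ["MODEL_NAMES", "ComparisonReport", "evaluate_model_run", "compare_models"]

TUNED_SVR_MODELS = {
    "svr-bes": "bes",
    "svr-co": "chimp",
    "svr-bes-co": "bes-co",
    "svr-ffa": "ffa",
    "svr-gwo": "gwo",
}
MODEL_NAMES = ("svr-default", *TUNED_SVR_MODELS, "dt", "rf")


def evaluate_model_run(
    df: pd.DataFrame,
    model: str,
    seed: int,
    features: Sequence[str] = ("ACE", "sex"),
    target: str = "sIL2R",
    test_fraction: float = 0.2,
    pop_size: int = 10,
    max_iter: int = 8,
    cv_folds: int = 5,
) -> dict:
    """One model, one replicate: split, fit/tune on train, score on test.

    Returns a dict with held-out ``rmse`` and ``r2`` (coefficient of
    determination, standardized units), plus the tuned hyperparameters and
    convergence trace where applicable.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    X = df.loc[:, list(features)].to_numpy(dtype=float)
    y = df[target].to_numpy(dtype=float)
    train_idx, test_idx = train_test_split(
        np.arange(len(y)), test_size=test_fraction, random_state=seed
    )
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]

    out = {"model": model, "seed": seed, "params": None, "trace": None}
    if model in TUNED_SVR_MODELS:
        optimizer = TUNED_SVR_MODELS[model]
        tuned = tune_svr(
            X_tr,
            y_tr,
            optimizer=optimizer,
            optimizer_config=budget_config(optimizer, pop_size=pop_size, max_iter=max_iter),
            protocol=EvalProtocol(scheme="kfold", k=cv_folds, seed=seed),
            seed=seed,
        )
        pipeline = tuned.model
        out["params"] = tuned.best_params
        out["trace"] = tuned.trace
        out["cv_rmse"] = tuned.best_fitness
        scaled_rmse, scaled_r2 = pipeline.score_scaled(X_te, y_te)
    elif model == "svr-default":
        # un-tuned reference: scikit-learn's stock settings on standardized data
        params = SvrHyperparams(C=1.0, eps_tube=0.1, gamma_kernel=1.0 / len(features))
        pipeline = fit_pipeline(X_tr, y_tr, params)
        out["params"] = params
        scaled_rmse, scaled_r2 = pipeline.score_scaled(X_te, y_te)
    else:
        # delegated tree ensembles at their library defaults, scored in the
        # same standardized units as the SVR arms
        scaler = _FoldScaler(X_tr, y_tr)
        est = (
            DecisionTreeRegressor(random_state=seed)
            if model == "dt"
            else RandomForestRegressor(random_state=seed)
        )
        est.fit(scaler.x(X_tr), scaler.y(y_tr))
        pred = est.predict(scaler.x(X_te))
        y_te_scaled = scaler.y(y_te)
        scaled_rmse = rmse(y_te_scaled, pred)
        scaled_r2 = r_squared(y_te_scaled, pred, "coefficient_of_determination")
    out["rmse"] = float(scaled_rmse)
    out["r2"] = float(scaled_r2)
    return out


@dataclass
class ComparisonReport:
    """Machine-readable analogue of a multi-model results section."""

    metrics: pd.DataFrame  # model, seed, rmse, r2
    hyperparams: pd.DataFrame  # model, seed, C, eps_tube, gamma_kernel
    run_matrix: pd.DataFrame  # seeds x models, held-out RMSE
    ttests: pd.DataFrame  # model_a, model_b, t, p, reject
    traces: dict = field(default_factory=dict)

    def metric_summary(self) -> pd.DataFrame:
        """Per-model mean/median of held-out RMSE and R^2 over the replicates."""
        return (
            self.metrics.groupby("model")[["rmse", "r2"]]
            .agg(["mean", "median", "std"])
            .sort_index()
        )


def compare_models(
    df: pd.DataFrame,
    models: Sequence[str] = ("svr-default", "svr-bes-co"),
    R: int = 10,
    seed_base: int = 0,
    ttest_kind: str = "pooled",
    alpha: float = 0.05,
    **run_kwargs,
) -> ComparisonReport:
    """Run ``R`` replicates of every model and compare all pairs by t-test."""
    models = list(dict.fromkeys(models))
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    if R < 2:
        raise ValueError("R must be at least 2")

    rows, hp_rows, traces = [], [], {}
    for model in models:
        for r in range(R):
            seed = seed_base + r
            res = evaluate_model_run(df, model, seed, **run_kwargs)
            rows.append(
                {"model": model, "seed": seed, "rmse": res["rmse"], "r2": res["r2"]}
            )
            if res["params"] is not None:
                p = res["params"]
                hp_rows.append(
                    {
                        "model": model,
                        "seed": seed,
                        "C": p.C,
                        "eps_tube": p.eps_tube,
                        "gamma_kernel": p.gamma_kernel,
                    }
                )
            if res["trace"] is not None and model not in traces:
                traces[model] = res["trace"]

    metrics = pd.DataFrame(rows)
    hyperparams = pd.DataFrame(
        hp_rows, columns=["model", "seed", "C", "eps_tube", "gamma_kernel"]
    )
    run_matrix = metrics.pivot(index="seed", columns="model", values="rmse")[models]

    ttest_rows = []
    for a, b in combinations(models, 2):
        res = compare_ttest(run_matrix[a], run_matrix[b], kind=ttest_kind, alpha=alpha)
        ttest_rows.append(
            {"model_a": a, "model_b": b, "t": res.t, "p": res.p, "reject": res.reject}
        )
    ttests = pd.DataFrame(ttest_rows, columns=["model_a", "model_b", "t", "p", "reject"])
    return ComparisonReport(
        metrics=metrics,
        hyperparams=hyperparams,
        run_matrix=run_matrix,
        ttests=ttests,
        traces=traces,
    )
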