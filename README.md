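# besco

Metaheuristic hyperparameter tuning for epsilon-SVR on biomarker cohorts:
Bald Eagle Search (BES), the Chimp Optimizer (CO), their sequential hybrid
BES→CO, and Firefly/Grey Wolf baselines, applied to predicting serum soluble
interleukin-2 receptor (sIL-2R, pg/mL) from serum angiotensin-converting
enzyme (ACE, U/mL) and sex in sarcoidosis-style cohorts.

## Who this is for

Serum sIL-2R tracks T-cell activation and is a candidate disease-activity
marker in sarcoidosis; ACE is the older, cheaper assay. A regression linking
the two supports non-invasive monitoring, but an RBF ε-SVR's accuracy hangs
on three hyperparameters — the penalty **C**, the insensitive-tube width
**ε**, and the kernel width **γ** — whose joint landscape is noisy and
non-convex. `besco` is for researchers who want to tune that landscape with
swarm metaheuristics under a reproducible, testable protocol, and for anyone
who needs clean, seedable implementations of BES, CO and the BES→CO hybrid
as bounded continuous optimizers in their own right.

## The method

All optimizers minimise an objective over a hard box, clip every proposed
position to the box, and accept a candidate only when it strictly improves
its agent (greedy acceptance), so best-so-far traces are non-increasing.

**BES** cycles three phases per iteration — select
(P_best + α·r·(P_mean − P_i)), search (spiral offsets
x(i) = sin θ(i)·r(i)/max|·| around the cyclic neighbour and swarm mean), and
swoop (hyperbolic-spiral contraction onto P_best). **CO** ranks agents into
α/β/γ/δ role groups each iteration, then hunts
(w·P_i + c1·rand·(Best − P_i) + c2·rand·(GroupBest − P_i)) and exploits
(P_i + δ·(Best − P_i) + ε·(GroupBest − P_i)). The **hybrid** runs BES to
completion, seeds CO with BES's ranked elite, and returns the better of the
two phases.

For tuning, a candidate (C, ε, γ) in the box C ∈ [10³, 10⁴], ε ∈ [0.001, 1],
γ ∈ [1, 20] is scored by the SVR's mean validation-fold RMSE under seeded
5-fold CV, with features and target standardized inside each training fold
(all reported RMSE is in standardized target units). See `docs/methods.md`
for the full model account, parameter defaults, and limitations.

## Worked example

```python
from besco import SVRTuner, gen_cohort

cohort = gen_cohort(n=200, seed=7)          # synthetic sarcoidosis-style table
tuner = SVRTuner.from_dataframe(cohort)     # features (ACE, sex) -> target sIL2R
results = tuner.fit(optimizer="bes-co", pop_size=6, max_iter=4, seed=7)
print(results.summary())
```

```
              SVR hyperparameter tuning results
================================================================
Optimizer:          bes-co
Objective:          mean CV RMSE (kfold, standardized target)
Target:             sIL2R
Features:           ACE, sex
N observations:     200
N evaluations:      126
----------------------------------------------------------------
C (penalty):        1020
epsilon (tube):     0.4277
gamma (RBF width):  8.901
----------------------------------------------------------------
CV RMSE:            0.3679
Train RMSE:         0.3100
Train R^2:          0.9039
Support vectors:    28
================================================================
```

The hybrid spent 126 cross-validated SVR fits inside the box and settled on a
moderate penalty with a wide tube (ε ≈ 0.43 standard deviations — robust to
the cohort's noise) and a fairly narrow kernel (γ ≈ 8.9, resolving the
threshold-like rise of sIL-2R with ACE). CV RMSE 0.368 means the tuned model's
typical cross-validated error is about a third of one sIL-2R standard
deviation; predictions come back in original units,
`results.predict(X)` → e.g. `[1447.0, 5517.8, 1570.7]` pg/mL for the first
three patients.

The optimizers are usable standalone:

```python
import numpy as np
from besco import Bounds, HybridConfig, benchmark_objective, hybrid_bes_co_run

sphere = benchmark_objective("sphere", 3)
res = hybrid_bes_co_run(sphere, Bounds(np.full(3, -5.0), np.full(3, 5.0)),
                        HybridConfig(seed=1))
res.best_fitness        # 0.0 — converged to the optimum
res.trace               # non-increasing best-so-far curve, length 201
```

A `besco` command-line tool wraps the pipeline: `besco simulate` writes a
synthetic cohort CSV, `besco tune` runs preprocess → tune → report for one
optimizer, `besco compare` runs several models under a shared replicate
schedule and writes metrics/run-matrix/t-test CSVs, and `besco stats` turns
any run matrix into a pairwise t-test table. Every command is reproducible
from its config and `--seed`.

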