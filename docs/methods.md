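# Methods

## The problem

Serum soluble interleukin-2 receptor (sIL-2R, pg/mL) tracks T-cell activation
and is a candidate activity marker in sarcoidosis; serum angiotensin-converting
enzyme (ACE, U/mL) is the older, cheaper marker. `besco` builds the pipeline
for predicting sIL-2R from ACE (plus a sex covariate) with an RBF
epsilon-support-vector regressor whose three hyperparameters — the penalty C,
the tube half-width ε, and the kernel width γ — are tuned by swarm
metaheuristics, chiefly a sequential hybrid of Bald Eagle Search (BES) and the
Chimp Optimizer (CO).

## Optimizers

All optimizers minimise a black-box objective over a hard rectangular box.
Three design rules are shared and fixed:

- **Clipping.** Every proposed position is clipped to the box before
  evaluation. The SVR search space is a hard box, so positions outside it are
  meaningless.
- **Greedy acceptance.** A candidate replaces its agent only when it strictly
  improves that agent's fitness. The update equations alone do not guarantee
  improvement; greedy acceptance is what makes every best-so-far trace
  non-increasing.
- **One seeded generator per run.** Every stochastic draw flows from a single
  `numpy` Generator, so a run is bit-reproducible from its seed.

### Bald Eagle Search

Three phases per iteration, one candidate per agent per phase:

1. *Select*: `P_best + α·r_i·(P_mean − P_i)`, with a scalar `r_i ~ U(0,1)` per
   agent (the simplest reading of "an arbitrary number in [0,1]") and gain
   `α ∈ [1.5, 2]` (default 2).
2. *Search*: `P_i + y_i·(P_i − P_{i+1}) + x_i·(P_i − P_mean)`, where the
   scalar offsets `x_i, y_i` come from a circular spiral:
   `θ_i = rand·π·a`, `r_i = rand·R·θ_i`, `x_i = sin(θ_i)·r_i / max|·|`,
   `y_i = cos(θ_i)·r_i / max|·|` (batch-max normalisation; an all-zero batch
   normalises to zeros). The neighbour index is cyclic so the last agent pairs
   with the first; a single-agent swarm drops the neighbour term.
3. *Swoop*: `rand·P_best + x1_i·(P_i − c1_i·P_mean) + y1_i·(P_i − c2_i·P_best)`
   with hyperbolic-spiral offsets (sinh/cosh in place of sin/cos) and
   `c1, c2 ~ U(1,2)` per agent.

Two radius dialects circulate for the spiral: a multiplicative form
`r = rand·R·θ` and the original BES form `r = θ + R·rand`. They genuinely
differ and no authority settles which is intended, so both are implemented
(`variant="as_printed"`, the default, vs `"canonical"`); every other rule is
shared. A further published variant sets the swoop angle recursively
(`θ = r`), which is circular as stated; the swoop here reuses the same
angle/radius construction as the search phase.

Defaults: population 50, 100 iterations, α = 2, a = 10, R = 1.5. Cost is
`pop × (1 + 3·iterations)` objective evaluations.

### Chimp Optimizer

Each iteration ranks agents by fitness and partitions the ranking into
contiguous blocks — alpha (best), beta, gamma, delta — of sizes differing by
at most one, remainders to the better groups, ties broken by original index.
Two moves follow, each greedy-accepted:

- *Hunt*: `w·P_i + c1·rand·(Best − P_i) + c2·rand·(GroupBest_i − P_i)`.
  Defaults `w = c1 = c2 = 1`: `w = 1` keeps the move a pure
  difference-vector update (so an agent sitting on both attractors is a fixed
  point), and unit gains leave the per-agent `rand ~ U(0,1)` draws as the
  effective step sizes. The draws are per-agent scalars, not per-dimension
  vectors — the scalar reading of the update — so moves are along attractor
  differences.
- *Exploit*: `P_i + δ·(Best − P_i) + ε·(GroupBest_i − P_i)` with
  `δ, ε ~ U(0,1)` per agent (ranges configurable).

A `variant="canonical"` switch replaces the hunt gains by the original ChOA
coefficient scheme `2·f·rand − f` with `f` decaying linearly from `l_const`
(default 2.5) to 0 across the run; the default variant ignores `l_const`.
Cost is `pop × (1 + 2·iterations)` evaluations when self-initialised.

### Hybrid BES → CO

BES runs to completion (exploration); its final population is ranked and the
top `carryover` fraction (default 1.0, i.e. the whole ranked population)
seeds CO, topped up with fresh uniform points if CO's population is larger.
Carried agents keep their fitness values, so the handoff costs no extra
evaluations. The result is the better of the two phases; the concatenated
trace is globally non-increasing; and with zero CO iterations the hybrid is
bit-for-bit a pure BES run under the same seed — a contract the tests check.

### Baselines

Firefly (Yang's formulation: attractiveness `β0·exp(−γ·d²)`, randomisation
decaying geometrically) and Grey Wolf (Mirjalili's: linearly decaying `a`,
positions averaged over the three leaders) are provided as canonical
comparison arms under the same bounds/trace contract. Both track the best
point in an archive since their canonical moves are not greedy.

## SVR fitting and the tuning objective

The regressor is the standard ε-insensitive RBF SVM,
`f(x) = Σ_j a_j K(x_j, x) + b`. The default loss exponent p = 1 delegates to
libsvm (scikit-learn); p = 2 (squared ε-insensitive loss) has no RBF solver
in scikit-learn and is solved here by L-BFGS on the representer-theorem
primal `½ aᵀKa + C Σ max(0, |y − f| − ε)²`, which is continuously
differentiable.

The libsvm solve is capped at 2,000 iterations. Adversarial candidate points
(C = 10⁴, ε ≈ 0, γ = 20 on noisy data) otherwise grind for ~a second each;
the cap truncates exactly those hopeless fits deterministically while leaving
well-conditioned fits untouched, and keeps a tuning run at tens of
milliseconds per candidate.

**Fitness.** A candidate (C, ε, γ) is scored by its mean validation-fold RMSE
under a seeded protocol — 5-fold CV by default, holdout optional. Features
*and target* are standardized inside each training fold only (no leakage):
the RBF kernel is scale-sensitive and ACE (~tens) and sIL-2R (~thousands)
differ by orders of magnitude, and the ε range [0.001, 1] is only meaningful
on a unit-variance target. All RMSE values this package reports are therefore
in standardized target units. The search box is the hard region
C ∈ [1000, 10000], ε ∈ [0.001, 1], γ ∈ [1, 20]; the box is searched in
original units by default, with a log₁₀-C option since C spans a decade.

The model-object surface follows the statsmodels idiom: `SVRTuner` holds the
data and protocol; `fit(optimizer=...)` runs the search and returns
`SVRTuningResults` with the tuned point, its CV RMSE, the convergence trace,
a final all-rows refit (predicting in original pg/mL units), and `summary()`.

## Preprocessing

Outliers are screened per numeric column by either the z-score rule
(|x − μ|/σ > 3, population σ — both the threshold and σ convention are
configurable; a constant column flags nothing) or the IQR rule (outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by linear interpolation — stated
because quartile dialects differ). Flagged cells are replaced by the mean of
the *unflagged* values: averaging over all points (the literal mean-imputation
formula) lets an extreme outlier contaminate its own replacement, so the
unflagged mean is the default and an `include_flagged` switch restores the
literal form. Cleaning never changes the row count or non-numeric columns,
and the report records every flag and replacement so case-by-case review
remains possible. Missing data are rejected at load time, not imputed.

## The synthetic cohort generator

The generator emulates the qualitative structure of a sarcoidosis biomarker
table; its defaults are fixed study conditions, not fitting targets.

- **ACE**: log-normal, median 45 U/mL, log-sd 0.45, truncated at ±2 sd in log
  space — right-skewed around the ≤68 U/mL reference range, with the
  truncation standing in for the finite dynamic range of the kinetic assay.
- **Link**: expected sIL-2R is `800 + 5000·Hill(ACE) + 1000·diagnosis` pg/mL,
  with `Hill(ACE) = ACE^h/(ACE^h + K^h)`, K = 60 U/mL, h = 25 — a switch-like
  threshold response near the upper reference range (computed as a logistic
  in log ACE for numerical stability). The steepness is deliberate: a gentle
  monotone link is fit near-optimally by stock SVR settings, leaving
  hyperparameter tuning nothing to improve; a threshold-type response is the
  regime in which tuning the kernel width genuinely matters.
- **Diagnosis and sex**: independent Bernoulli draws (prevalence and balance
  0.5). The disease shift makes sIL-2R clearly discriminative of diagnosis
  (point-biserial ≈ 0.24) while sex carries no signal — and since diagnosis
  is *not* a predictor, the shift is also the cohort's irreducible error.
- **Noise**: multiplicative log-normal with σ = 0.06, mean-preserving
  (`exp(σZ − σ²/2)`), so sIL-2R stays positive, its spread grows with its
  mean, and `noise_sd = 0` yields an exactly deterministic table.

What the generator does **not** emulate: the real cohort's moments, missing
data, assay censoring at the reporting limits, or any ACE–diagnosis
association. Tests passing on this generator show the pipeline's machinery is
correct under its stated conditions; they are not evidence about clinical
data.

The planted-outlier fixture is deliberately simpler: ACE uniform on
[25, 85] U/mL and sIL-2R exactly linear in ACE, noiseless. Both columns are
then uniform — bounded and light-tailed — so neither detector can fire on the
clean table (even a perfect Gaussian naturally exceeds the 1.5·IQR fences
~0.7% of the time, and a diagnosis-shifted mixture leaves a sparse upper tail
that the IQR fence occasionally clips; the fixture avoids both). Plants at
50× the column median then sit unambiguously outside every fence.

## Comparison harness and replicate statistics

`compare_models` runs every requested arm — stock-settings SVR, the five
tuned SVRs, decision tree, random forest (library defaults, recorded verbatim)
— under one shared schedule: per replicate seed, an 80/20 train/test split;
tuning/fitting on the training part only (tuned arms use seeded 5-fold CV
inside the training part); scoring on the held-out part in standardized
units. Per-run RMSE vectors feed two-sided two-sample t-tests for every model
pair, the classic pooled (equal-variance) test by default with Welch
selectable, rejecting at p < 0.05. All pairs are reported explicitly since
"reference algorithm" layouts are ambiguous. R² is reported as the
coefficient of determination 1 − SSE/SST by default; the Pearson-r and
squared-Pearson conventions are implemented and labelled, because the three
diverge off the diagonal and published tables rarely say which was used.

## Problem sizes and numerical choices

- Tuning runs in tests and the acceptance script use a desk-scale budget of
  population 6 and 4 iterations per phase (126 evaluations for the hybrid)
  on n = 200 cohorts with 5-fold CV — enough for the optimizer to clear
  random search decisively while keeping a 20-replicate experiment in
  minutes. Benchmark-function runs use the stock population 50 / 100
  iterations.
- Batch-max normalisation of the BES offsets guards 0/0 → 0.
- Group partition ties break by original agent index (stable sort), making
  runs reproducible even with duplicated fitness values.
- MAPE excludes rows with zero actual value (logged count) rather than
  dividing by zero; the pooled t-test returns t = 0, p = 1 for identical
  constant samples and raises when both samples are constant but unequal.
- Degenerate inputs (single-agent swarms, swarms smaller than the group
  count, constant columns, all-flagged columns) follow the documented
  contracts rather than erroring where a sensible definition exists.

## Known limitations

- The update rules are contractions around the incumbent best once the swarm
  collapses; there is no scale-free noise injection, so very-high-precision
  polishing on hard multimodal functions is not the design point.
- The p = 2 loss path solves the primal to L-BFGS tolerance, not to the
  KKT precision of libsvm's SMO; it is exercised, not battle-hardened.
- CV-selected hyperparameters inherit winner's-curse optimism on small
  cohorts; the harness's held-out scoring quantifies but does not remove it.
- The t-test treats per-seed RMSE values as independent replicates although
  they share the cohort; this mirrors common practice in the optimizer
  literature and is noted rather than corrected.
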