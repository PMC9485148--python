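# Methods

## The estimation problem

A juvenile's chronological age (CA) is estimated from the mineralization
stages of the seven left-mandibular permanent teeth (FDI 31–37), each
graded on the ordinal Demirjian scale A–H. Two classical estimator
families operate on stage data through sex-specific score tables: age-sum
tables map each (tooth, stage) cell to a score in years and sum the seven
scores directly into a dental age (DA); maturity tables sum per-tooth
maturity points and pass the total through a piecewise-linear
score-to-age conversion curve. The package's evaluation vocabulary is the
field's: age deviation AD = DA − CA (positive = overestimation), MAE
optionally restricted to CA below a cap (18 or 16 years), MSE/RMSE/R²,
paired t-test of DA against CA, and Cohen's kappa for rater agreement.
Standard deviations use the n−1 denominator throughout; R² is
1 − Σ AD² / Σ (CA − mean CA)².

## Table refitting by non-intercept regression

A published score table is adapted to a local cohort by least squares
through the origin: per sex, CA is regressed on stage-score predictors
with no intercept term, and the coefficients are folded back into the
table. Two design matrices are implemented:

* **per_tooth** (default): seven columns, one per tooth, holding the base
  table's score for the attained stage; the coefficient bₜ rescales tooth
  t's whole row: modified(t, s) = bₜ · base(t, s). This is the classical
  "reweight each tooth's parameters" procedure. Note that a positive
  rescaling preserves a row's sign pattern — published age-sum rows can
  carry negative scores for early stages, so refit output tables can too.
* **per_cell**: one 0/1 indicator column per (tooth, stage) cell observed
  in the cohort; the coefficient is the modified cell score, and cells
  never observed stay undefined (ABSENT), matching the dashed cells of
  printed tables (stages completed before the cohort window opens).

The per_cell design is structurally rank deficient: every record activates
exactly one cell per tooth, so each tooth's indicator block sums to the
all-ones vector and cell scores are identified only up to between-tooth
shifts that cancel in every complete record's sum. All least-squares
solutions therefore produce identical fitted values and identical
predictions for complete records. To pin down the *printed* table, the fit
is anchored: among the least-squares solutions the one closest to the base
table's scores is reported (b = b₀ + lstsq(X, y − Xb₀)). With a noise-free
cohort generated from a known table and that table as the anchor this
yields exact cell recovery, which the tests exploit. The low-level solver
(`fit_nonintercept_ols`) without an anchor treats rank deficiency as an
error and names the dependent columns.

The default strategy is per_tooth rather than per_cell for a substantive
reason beyond fidelity to the classical procedure: under the synthetic
cohort's generating mechanism (below), the conditional mean of age given
the stage vector is nearly additive across teeth, so a free per-cell fit
is close to the Bayes predictor and leaves no room for any learner to
improve on it; the per-tooth fit is the realistic, constrained linear
baseline whose structural bias nonlinear learners can beat — the regime
the method-comparison analyses are about.

Whether a refit should use a training split or the full sample is a design
choice; the pipeline follows the convention of fitting score tables on the
full cohort (score-model reports are in-sample) while learners only ever
see the training split, and the manifest records both choices.

## Native learners

All tree learners share one CART base: squared-error impurity, split
candidates at midpoints between consecutive distinct feature values, ties
broken toward the lower feature index then lower threshold, and
*best-first* growth — a priority queue of frontier nodes ordered by
impurity decrease — which is the standard way to honor a `max_leaf_nodes`
budget. Features are the ordinal codes [sex (0 female / 1 male), seven
stage codes A=1…H=8, MISSING=0]; ordinal rather than one-hot encoding
because staging is ordinal and threshold splits exploit the ordering.

Defaults follow the configuration reported in the staging literature:
trees with depth ≤ 10 and ≤ 50 leaves; decision tree min_samples_leaf 2;
GBDT and the forests min_samples_leaf 1 with 100 estimators; GBDT learning
rate 0.1 and subsample fraction 1.0 (no stochastic subsampling); AdaBoost
learning rate 1.0 with the decision-tree base; KNN with k = 5 and
Euclidean distance, ties at the k-th distance broken by training order.

* **GBDT**: F₀ = mean(y); each round fits a tree to the residuals and adds
  it scaled by the learning rate. With squared-error leaf values and
  learning rate ≤ 1 the training MSE is non-increasing by construction,
  and the fitted model records its per-round MSE path so tests can assert
  it.
* **Random forest / extra trees**: averaged trees over bootstrap resamples
  (forest) or over the full sample with one uniform random threshold per
  candidate feature per node (extra trees). Split randomization, bootstrap
  and per-node feature subsampling are independent switches, so a single
  un-randomized tree degenerates exactly to the plain CART fit.
* **AdaBoost.R2** (linear loss): rounds resample the training set by the
  current weights, score the tree by the weighted average linear loss
  L̄ = Σ wᵢ|errᵢ|/max|err|, stop when L̄ ≥ 0.5, and update
  wᵢ ← wᵢ·β^(lr·(1−Lᵢ)) with β = L̄/(1−L̄); prediction is the weighted
  median with learner weights lr·ln(1/β). When the weights are exactly
  uniform the resample would be pure noise, so the raw sample is fitted
  instead — this also makes a one-round ensemble identical to the base
  tree. A perfect round is kept with an ε-guarded weight and ends
  boosting.

Every learner is deterministic given (data, config, seed); models
serialize to versioned JSON whose reload reproduces identical predictions.
Against scikit-learn at matched hyperparameters on a fixed synthetic
cohort (n = 1000), the native CART's test MAE is typically identical and
the ensembles agree within ~1%.

## The synthetic cohort generator

No public staging dataset matches the package's target population, so all
pipeline-level validation runs on synthetic cohorts with known ground
truth. The generator is a threshold model on a latent developmental
clock:

* Each (sex, tooth) carries a row of stage-attainment ages τ_A…τ_H — the
  mean age at which the stage is first reached — strictly increasing where
  defined. Stages whose τ is undefined were reached before the cohort's
  2-year lower bound and act as a floor (the subject is at least at that
  stage); the floors mirror the undefined early cells of the builtin
  tables so that generated cohorts never request a score the tables do not
  define.
* Each subject draws one shared tempo offset δ ~ N(0, offset_sd) — whole
  dentitions run early or late together, which correlates teeth within a
  subject — and each tooth an independent jitter ε ~ N(0, tooth_jitter_sd).
  The attained stage is the highest s with τ_s ≤ age + δ + ε.
* Ages are sampled uniformly within one-year bins; the default bin counts
  reproduce the reference sample layout (n = 1477; 833 female, 644 male),
  and `scaled_spec(total)` shrinks that layout proportionally.

Default parameters are versioned constants in
`src/dentalage/data/maturation_defaults.json` (version 2), not magic
numbers in code. The attainment rows encode tooth development that is
fast early and slows toward apex closure, with *irregular* per-tooth
tempo — alternating spurts and plateaus, out of phase between teeth —
because stage progression in real dentitions is not linear in age, and
that irregularity is precisely what gives nonlinear learners their edge
over a rescaled score table. Female trajectories run 0.35 years earlier
than male; the second molar completes last (τ_H ≈ 15 years), so the
oldest two bins are mostly information-free (all-H patterns), as in real
cohorts. Noise scales offset_sd = tooth_jitter_sd = 0.4 years were
calibrated once so that the builtin score tables show an AD spread of
≈ 0.85–0.9 years and refit score models reach MAE ≈ 0.55–0.8 years — the
operating range reported for score-table methods on real cohorts — while
gradient boosting retains a reproducible test-MAE advantage over the
per-tooth linear model (observed in 10/10 generation seeds). The
generator produces no unscorable (MISSING) teeth; MISSING handling in the
estimators is exercised by unit tests directly.

What the generator does *not* emulate: secular trends, ethnicity
structure, rater error (stages are exact draws from the model), missing
or extracted teeth, and any correlation between staging error and age.
Passing pipeline tests on synthetic cohorts therefore demonstrates
correctness of the machinery and the qualitative method ordering, not
clinical accuracy on any real population.

`generate_from_score_table` replaces the drawn CA with the table's score
sum plus optional Gaussian noise (clipped to the valid age window), so the
cohort satisfies the additive score model by construction; it backs the
refit recovery tests.

## Pipeline and reproducibility

`run_study` computes score-model reports on the full cohort and learner
reports on a seeded 3:1 train/test split (the conventional ratio; it is a
parameter). One root seed fans out to stage seeds via
`SeedSequence(root).generate_state(...)`, one word per named stage reduced
mod 2³¹, so the split and each learner are independently reproducible.
Reports are written as CSV and sorted-key JSON with stable formatting;
re-running with the same seed reproduces byte-identical report files, and
the manifest stores config, seeds, per-stage timings and SHA-256
checksums. Problem sizes in the test suite (cohorts of 200–1477, one
full-size 10-seed comparison) were chosen to exercise the full default
configuration while keeping a complete run in tens of seconds.

## Known limitations

* The builtin modified tables are transcriptions of published values; the
  package does not claim to reproduce the regression that produced them,
  and the exact design matrix used by the original authors (per-tooth vs
  per-cell) is not documented.
* Maturity-conversion curves for the classical Demirjian method are not
  bundled (they are not in the public domain of this package's sources);
  users supply them as JSON.
* AdaBoost.R2 with weighted resampling is inherently sample-based; two
  implementations with different resampling streams agree only
  statistically, which is why its oracle tolerance is looser than the
  other learners'.
* Backpropagation networks, SVR and the gradient-boosting frameworks
  LightGBM/XGBoost/CatBoost are out of scope; the native learners cover
  the tree-ensemble core of the method-comparison design.
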