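# Methods

`icehab` implements a climate-sensitivity analysis of breeding-habitat
models for ice-obligate Antarctic seals: ensembles of presence–absence
habitat models built on balanced bootstrap replicates, cross-model
variable importance, and an expert-score-weighted ranking (the *change
importance product*) that highlights covariates which are both
influential and likely to change under climate change. All stages are
exercised end to end on synthetic data with known generating structure.

## The analysis pipeline

Input is an occurrence table — one row per record with a binary presence
flag and a vector of environmental covariates (ice metrics, distances to
physical and biological features, temperatures) — plus a rater × variable
climate-score sheet.

1. **Collinearity screening.** Covariates are screened by variance
   inflation factor, VIF_j = 1/(1 − R²_j), with R²_j from an OLS
   regression of covariate j on all others. Screening is stepwise: the
   single worst variable is removed (alphabetical tie-break), VIFs are
   recomputed, and removal repeats until all VIF ≤ 10. Stepwise removal
   is used rather than one-shot exclusion of everything above threshold
   because shared collinearity inflates several VIFs at once and one-shot
   removal over-prunes; each removal is logged so the alternative is
   recoverable. Perfect linear dependence is reported as an unbounded
   flag (`inf`), not an overflowed float.

2. **Balanced hold-out.** A fraction (default 20%) of the *presence*
   records — `floor` of the fractional count — plus an equal number of
   absences are withheld uniformly at random as the test set. The
   fraction is interpreted against presences, not all records, because
   the test set is class-balanced by construction; an explicit presence
   count can override the fraction. Hold-out records are used only for
   goodness of fit, never for fitting or importance.

3. **Balanced bootstraps.** Each training replicate contains *every*
   training presence exactly once plus an equal-size uniform sample of
   absences — without replacement when the absence pool suffices, with
   replacement otherwise. This compensates for the severe class imbalance
   of such surveys (presences ≪ absences): without balancing, models
   optimise on predicting absences.

4. **The three learner families.** Each bootstrap is fed to a random
   forest (RF), a boosted regression tree (BRT) and a maximum-entropy
   presence/background model (MAXENT). Each learner is tuned per
   bootstrap by grid search with k-fold cross-validation (default k = 10,
   fold sizes differing by at most one): out-of-fold probability
   predictions are pooled and scored with R² = 1 − SS_res/SS_tot against
   the 0/1 labels, and the best candidate is refit on the whole replicate.
   Ties go to the simpler candidate (fewer trees, shallower depth, larger
   regularization), then declaration order. R² of pooled out-of-fold
   probabilities is used as the selection metric even for the binary
   outcome so that tree and Maxent members are tuned identically; a
   squared-correlation variant is available by flag.

   RF and BRT are backed by scikit-learn. Default grids (configurable)
   follow common ecological practice: RF varies the covariates tried per
   split over {⌈√p⌉, ⌈p/3⌉, p} at 500 trees; BRT varies learning rate
   {0.01, 0.1}, interaction depth {1, 3} and trees {100, 500}; MAXENT
   varies the regularization multiplier {0.5, 1, 2}.

5. **Importance and the change importance product.** Permutation
   importance (drop in AUC under column shuffling, 5 independent shuffles,
   evaluated on the member's own bootstrap records) is used for RF and
   MAXENT; split-gain percentage contribution for BRT. Per member, raw
   importances are clipped at zero and normalized to the simplex
   (*proportional importance*), then averaged per learner family across
   bootstraps. The climate change score — each rater's 0–3 rating of how
   strongly a covariate is expected to change, averaged over raters —
   multiplies the mean proportional importance to give the per-family
   change importance product (CIP); variables are ranked descending by
   the unweighted mean CIP across the three families (no weighting is
   applied because none is justified a priori). CIP lies in [0, 3] by
   construction.

6. **Evaluation and partial dependence.** Every member is scored on the
   balanced hold-out set with both AUC and R², and means ± SD are
   reported per family (both metrics are emitted for every family so
   either reporting convention can be followed). Partial dependence
   sweeps a covariate over 50 evenly spaced points between its 1st and
   99th percentile (avoiding extrapolated tails), averaging predictions
   over the data; the uncertainty band is the SD pooled across *all*
   members of all families, so it mixes bootstrap-sampling and
   between-model uncertainty deliberately. Per-family curves are also
   emitted.

## The maximum-entropy learner

MAXENT is implemented in-repo from its convex objective. With features
f(x) (min–max rescaled on the training sample, then expanded into linear,
quadratic, pairwise-product and hinge classes; hinge knots at equally
spaced quantiles), the model is the Gibbs density π(x) ∝ exp(w·f(x)) over
the background records, fitted by

    min_w  −mean_presence[w·f(x)] + log Z(w) + Σ_j β_j |w_j|,

Z(w) the background normalizer. The weights are split into nonnegative
parts (w = u − v), turning the L1 term linear, and solved by
box-constrained L-BFGS-B to projected-gradient tolerance 1e-6. At β = 0
the optimum satisfies the moment constraint (π-weighted background
feature mean = presence feature mean), which the tests verify to 1e-4.
The per-feature penalty is β_j = m · sd_j / √n_presence with multiplier m,
the conventional sample-size-aware scaling. Probability of presence uses
the relative occurrence rate r(x) = exp(w·f(x))/Z weighed against a
prevalence τ (training prevalence by default, 0.5 on balanced
bootstraps): P = τr / (τr + 1 − τ).

Feature scaling constants come from the full training sample rather than
the background alone: background-only ranges clip separable presences
onto a single feature value and destroy their ordering.

The classifier's background is the whole training replicate — absences
*and* presences — not the absences alone. With an absence-only
background, presences occupying feature regions the background never
reaches make the penalised objective unbounded below (the weights
diverge); including the presences guarantees that the background maximum
dominates the presence mean in every direction, so the optimum exists.
This mirrors standard Maxent practice, where the background is a sample
of the whole landscape including presence locations. The lower-level
`fit_maxent` keeps the generic presence/background signature for any
caller-supplied matrices.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:

- exact class totals (presences ≪ absences); labels are
  Bernoulli-logistic in a sparse set of *driver* covariates, conditioned
  on the exact totals by rejection sampling with a force-relabel fallback
  (with a warning) for degenerate probabilities;
- correlated continuous covariates from a multivariate normal with a
  user-specified PSD correlation matrix; positive right-skewed
  "distance-like" covariates by exponentiating a Gaussian column (the
  linear predictor uses the latent Gaussian, so the presence link remains
  monotone in the stored covariate);
- manufactured near-duplicates (`copy = source + N(0, σ)`), so the VIF
  screen has known offenders;
- fixture rater sheets with uniform 0–3 scores and optional unanimous-0/3
  columns for exact oracle means.

A single root seed spawns per-stage child generators, so covariate
generation, labelling and scoring are independently reproducible.

What the generator does **not** emulate: spatial autocorrelation, raster
geometry, real ice/ocean physics, and covariate distributions beyond
(transformed) Gaussians. Passing tests therefore demonstrate the
statistical machinery — balanced sampling, tuning, importance
aggregation, ranking — not transferability to real survey data, where
spatial structure can inflate apparent performance.

The absence:presence ratio is a free parameter (real surveys do not pin
it); the test fixtures use 10:1.

## Numerical and design choices

- VIF: `inf` flag when 1 − R² < 1e-12; constant columns rejected with a
  diagnostic; screening stops with a warning below 2 remaining variables.
- Negative permutation importances are clipped to zero before
  normalization so proportions form a simplex (required for CIP); the
  clipping is documented in the long-format output. A member whose raw
  importances are *all* zero (e.g. a fully shrunk MAXENT member) carries
  no ranking information and contributes uniform proportions with a
  warning; calling `proportional_importance` directly on an all-zero
  vector raises.
- Importance SD across bootstraps uses the sample SD (ddof = 1, zero for
  a single bootstrap); partial-dependence SD across members uses the
  population SD so a single member gives exactly zero.
- CIP ranks are dense on the overall mean product, descending; ties are
  ordered alphabetically and flagged.
- `run_species_analysis` is resumable at stage granularity: every stage
  is an importable function taking the previous stage's outputs, and the
  manifest records counts, per-stage seeds and table digests so a rerun
  can be verified bit-for-bit. No disk-checkpoint machinery is provided.
- "Strong driver" in the performance property tests is defined on the
  generator side: a coefficient of 4 on a standardised covariate
  (intercept −2) puts the Bayes-optimal AUC near 0.96, so hold-out
  AUC > 0.9 is attainable in principle by every family.

## Problem sizes in the test suite and acceptance script

Fits are deliberately desk-scale (the package's own choice of test
conditions): the parameter-recovery suite uses 500 presences, 10
covariates, 50 bootstraps and single-candidate grids with 100-tree
forests; the full 500-bootstrap × 3-family protocol is exercised with
miniature per-fit data (≈25 presences per bootstrap, 10-tree ensembles);
the null-model check uses zero generating coefficients at 8 covariates.
All seeds are fixed or derived from the acceptance script's `--seed`.

## Known limitations

- In-bag permutation importance on balanced bootstraps (which share all
  presence records) concentrates spurious importance on whichever
  covariate has the largest accidental in-sample association; this is a
  structural property of the design, strongest for the sparse MAXENT
  member, and is why the null-model check allows a Monte-Carlo band (two
  standard errors of the bootstrap spread) around twice the uniform
  share. Evaluating importance on other record sets does not remove it.
- CV-R² tie-breaking compares float scores for exact equality (within
  1e-12); genuinely tied non-identical candidates are rare off the
  degenerate cases it is designed for (fully shrunk members).
- The expert score sheet is an input, never inferred: real elicited
  scores are study-specific and unpublished beyond worked examples, so
  baking any in would fabricate data.
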