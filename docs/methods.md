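# Methods

## Model and conventions

The subject-level quantity of interest is the wildtype voxel fraction
x ∈ [0, 1]: the proportion of predicted tumor voxels labelled IDH-wildtype
after ensembling the per-fold segmentations. Labels follow the fixed
convention 0 = background, 1 = mutant, 2 = wildtype; IDH-wildtype is the
positive class (y = 1) everywhere, which makes recall identical to the
wildtype-class accuracy by definition.

x is stored and modelled as a *fraction*, never a percentage. The logistic
slope β is scale-dependent and the N(0, 1) "informative" prior is only
informative on a bounded covariate; on a 0–100 scale it would be
effectively flat. Any percent-scale I/O is converted at the boundary.

Calibration model: P(y = 1 | x) = logistic(α + βx), fitted two ways.

* **LR (maximum likelihood).** Newton-type fit via `statsmodels.Logit`;
  standard errors from the observed information. Complete (and quasi-)
  separation is detected *exactly* beforehand — with one covariate the MLE
  diverges iff the class-conditional ranges of x do not overlap — and a
  separated fit is flagged with NaN estimates rather than returned as
  divergent numbers. The pipeline then scores the LR route with the
  non-informative Bayesian fit, whose priors regularise separation, and
  logs a warning.
* **BLR (Bayesian).** Posterior ∝ likelihood × N(α; 0, σ²) × N(β; 0, σ²),
  with σ² = 1 (informative) or σ² = 1000 (non-informative; "variance"
  means variance, not SD). Sampling is adaptive random-walk Metropolis:
  the proposal covariance is the Laplace approximation at the posterior
  mode (found by trust-region Newton) scaled by 2.38²/d with d = 2; chains
  start at the mode plus 2× overdispersed Gaussian jitter; each chain's
  scalar step scale is Robbins–Monro-adapted during warm-up toward 35%
  acceptance (near-optimal for a 2-D Gaussian-like target) and frozen
  afterwards. Defaults: 4 chains × 2000 kept draws after 1000 warm-up
  iterations, deterministic seed. Rank-normalised split-R-hat and bulk ESS
  (ArviZ) are computed on every fit; R-hat ≥ 1.01 on either parameter
  raises a `ConvergenceError` carrying the diagnostics — the standard
  remedy is rerunning with a larger draw budget.

The confidence score of a subject is the fitted curve at the subject's x.
For BLR this is the posterior-predictive mean over the stored draws: it is
the Bayes estimate of P(y = 1 | x) under squared-error loss, which is
exactly the loss the Brier score measures; the posterior median and a
central band are available (`predict_median`, `predict_interval`) for
transparency. `p_predicted_class` — the probability of the class actually
called — is the clinician-facing number; the Brier score always evaluates
the positive-class probability `p_wildtype`, because treating the raw
wildtype fraction as a score is only coherent on that scale.

## Subject calls

Fold ensembling is a per-voxel plurality vote over {0, 1, 2}; vote ties are
broken by the fixed priority 2 > 1 > 0 (prefer calling tumor over
background, and the prevalent class over the rare one) and tallied. The
subject call is wildtype iff n₂ > n₁; an exact tie is called wildtype with
a flag that propagates into reports rather than being silently absorbed.
This is equivalent to thresholding x at 0.5.

In counts-only mode (no volumes), per-fold count rows of one subject are
pooled by summation — vote pooling. This is not identical to per-voxel
plurality voting (which requires voxel alignment), but both reduce to the
same call in the regime that matters, where fold disagreement is small
relative to the class margin.

## The synthetic cohort generator

The generator emulates the statistics of a trained segmentation network's
outputs, not the images: there are no intensities, contrasts or site
effects, and no network surrogate. Per subject it draws

* a true label, wildtype with probability 1904/2481 ≈ 0.768 (the class mix
  of the published multi-site cohort whose conventions this package
  mirrors);
* a latent wildtype fraction from Beta(0.9, 4.5) (mutant-truth; mass near
  0) or Beta(5.5, 1.1) (wildtype-truth; mass near 1). These defaults were
  fixed once, from closed-form Beta tail and variance calculations, to
  produce the regime reported for the real cohort: latent subject accuracy
  ≈ 97%, a clearly bimodal x mixture, a miscalibrated raw-x Brier ≈ 0.05
  and a calibrated Brier of a few hundredths;
* a tumor size (voxel count) from log-normal(μ = 9.0, σ = 1.0) — median
  ≈ 8 100 voxels, i.e. ≈ 8 cm³ at 1 mm³ resolution, spanning roughly 1 to
  150 cm³ across subjects;
* per fold (default 5), each tumor voxel's class flipped independently
  with probability 0.05.

Geometry is a filled ellipsoidal blob at the volume centre (exactly the
drawn number of voxels, taken in distance order). Only voxel counts matter
downstream; the blob exists to exercise the NIfTI path.

Randomness is counter-based: subject i of cohort k under seed s draws from
`default_rng([s, k, i])`, so enlarging a cohort never perturbs earlier
subjects and identical configs are bit-identical.

The counts-only path marginalises the voxel geometry analytically: a base
voxel's post-ensemble class flips with probability P(Binom(F, p) ≥ F/2)
(mutant→wildtype; ties to wildtype) or P(Binom(F, p) > F/2)
(wildtype→mutant), so ensembled counts are sums of two binomials. This is
distribution-identical to running the voxel path plus per-voxel voting,
and is what the fast pipeline and the acceptance script use.

What passing tests on this generator do **not** show: robustness to
scanner/protocol shift, segmentation failure modes correlated across folds
(flips here are independent), site-specific prevalence, or any property of
the upstream network. They validate the statistical pipeline given
label-map inputs with the assumed bimodal structure.

## Evaluation and pooling

Metrics: accuracy, per-truth-class accuracy, precision/recall/F1
(wildtype positive), and AUC as the midrank pairwise statistic (equivalent
to the trapezoidal ROC area), computed via scikit-learn and cross-checked
in the tests against brute-force confusion-matrix and pairwise oracles.
Multi-cohort pooling is exact — confusion cells are summed and metrics
recomputed — with count-weighted averaging of per-cohort rows retained as
a separate reporting utility (`pooled_weighted`), since published tables
are typically poolable only that way. Rounding to one decimal happens only
at the reporting boundary.

The two-stage protocol enforces cohort disjointness by subject id and
fits all calibrators on the fit cohort alone; the evaluation cohort
contributes nothing to any fit (verified by a perturbation test).

## Problem sizes and numerical choices

The default run mirrors the published held-out design: 1236 subjects to
fit the calibration, 164 to evaluate it. The test suite's Bayesian
interval-coverage study uses 200 replicates at n = 500 with the default
sampler budget (~1 minute total); the parameter-recovery checks use
n = 5000. Degenerate inputs are handled explicitly: empty tumors raise and
are excluded with a logged reason; single-class cohorts make AUC/precision
"undefined with reason" rather than NaN; separation is flagged, not
propagated as divergent estimates.

## Known limitations

* Independent per-voxel, per-fold flip noise understates the spatially and
  across-fold correlated errors of real segmentation networks; real
  calibration curves are likely flatter than the synthetic ones.
* The calibration uses a single covariate and fixed Gaussian priors; no
  hierarchical priors, covariate extensions, or multiclass molecular
  markers.
* Counts-mode fold pooling (summation) is an approximation to per-voxel
  plurality voting; with few folds and near-0.5 fractions the two can
  disagree.
* The random-walk Metropolis sampler is adequate for this 2-parameter,
  well-conditioned posterior; it is not a general-purpose sampler.
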