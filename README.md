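# idhcal

Confidence-calibrated subject-level IDH calls from voxel-wise glioma
segmentations.

## The problem

The IDH (isocitrate dehydrogenase) mutation status of a diffuse glioma is a
key molecular marker for prognosis and therapy, normally determined from
biopsy tissue. Voxel-wise segmentation networks can predict it
non-invasively from MRI: each tumor voxel is labelled IDH-mutant (1) or
IDH-wildtype (2) against background (0), and the subject-level call is the
majority voxel class. But a hard call without a reliability measure is hard
to act on clinically. `idhcal` implements the downstream statistical
pipeline that turns such voxel-wise label maps into a call **with a
calibrated confidence score**:

1. **Fold ensembling** — per-voxel plurality vote across the label maps of
   the cross-validation fold models (ties broken wildtype > mutant >
   background).
2. **Wildtype voxel fraction** — x = n₂ / (n₁ + n₂), the single covariate
   of the calibration model. Its distribution over subjects is strongly
   bimodal: mutant-truth subjects near 0, wildtype-truth near 1.
3. **Majority vote** — call wildtype iff x > 0.5 (exact ties go to
   wildtype, the prevalent positive class, and are flagged).
4. **Calibration** — on a held-out cohort, fit

   P(y = 1 | x) = 1 / (1 + exp(−(α + βx)))

   with y = 1 for IDH-wildtype, by maximum likelihood (LR) and by Bayesian
   logistic regression (BLR) with independent Gaussian priors α, β ~
   N(0, σ²): σ² = 1 (informative, regularising) and σ² = 1000
   (non-informative, data-dominated). BLR confidence is the
   posterior-predictive mean of the curve over MCMC draws.
5. **Evaluation** — on a second, disjoint cohort: Brier score
   mean((p − y)²) for the raw fraction and each calibrated score, plus
   accuracy, per-class accuracy, precision, recall, F1 and AUC (wildtype
   positive).

A synthetic cohort generator (class-conditional Beta mixtures over x,
log-normal tumor sizes, per-fold voxel flip noise) stands in for the
trained network's outputs, so the entire pipeline is testable at desk
scale.

## Worked example

```python
from idhcal import (CohortSimConfig, simulate_counts, records_from_counts,
                    records_to_frame, two_stage_protocol)

def cohort(n, key, prefix):
    _, counts = simulate_counts(CohortSimConfig(
        n_subjects=n, seed=1, cohort_key=key, subject_prefix=prefix))
    recs = records_from_counts(counts[["subject_id", "n_mutant", "n_wildtype"]],
                               counts[["subject_id", "true_label"]])
    return records_to_frame(recs)

report = two_stage_protocol(cohort(1236, 1, "A"), cohort(164, 2, "B"), seed=1)
print(report.lr.summary())
print(report.blr_noninformative.summary())
```

prints

```
Logistic calibration (maximum likelihood)
  n = 1236, wildtype = 944
  converged = True, separated = False
  param       estimate     std err
  alpha        -6.9803      0.6389
  beta         15.6468      1.2540
  log-likelihood = -95.653
Bayesian logistic calibration, prior N(0, 1000)
  n = 1236, chains = 4, draws/chain = 2000, seed = 2
  param         mean        sd      2.5%     97.5%   R-hat      ESS
  alpha      -7.0694    0.6513   -8.3874   -5.9139  1.0026     1096
  beta       15.8704    1.2764   13.5805   18.4798  1.0034     1097
  mean acceptance = 0.33
```

The large positive slope says the wildtype fraction is highly informative;
the non-informative posterior mean essentially reproduces the MLE (the
prior contributes negligible information at n = 1236), while the
informative N(0, 1) fit (not shown) shrinks the slope toward zero. Scoring
the held-out 164-subject cohort:

```python
for method, b in report.brier_eval.items():
    print(f"Brier({method}) = {b:.4f}")
```

```
Brier(raw_x) = 0.0580
Brier(lr) = 0.0278
Brier(blr_informative) = 0.0264
Brier(blr_noninformative) = 0.0277
```

The raw fraction, read naively as a probability, is miscalibrated; the
fitted curves roughly halve the Brier score. The held-out accuracy here is
93.9% with AUC 0.99 — and AUC is identical for raw and calibrated scores,
since a monotone calibration cannot change ranks.

## Command line

```sh
idhcal simulate  --config cfg.yaml            # write a synthetic cohort
idhcal call      --counts counts.csv --truth truth.csv --out subjects.csv
idhcal calibrate --subjects subjects.csv --prior-variance 1000 --out fit.json
idhcal evaluate  --subjects subjects.csv --out metrics.json
idhcal run-all   --config cfg.yaml            # the whole two-stage pipeline
```

`run-all` accepts three input modes — `simulate`, `volumes` (per-fold NIfTI
label maps named `<subject>_fold<k>.nii.gz`) and `counts` (a CSV of
per-class voxel counts; no imaging dependency) — and writes `subjects.csv`,
`metrics.json`, `reliability.csv`, `run.log` and a `manifest.yaml` with the
config hash. Exit codes separate validation (2), cohort leakage (3), MCMC
non-convergence (4) and I/O (5) failures.

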