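# preecv

Tools for the **PRE-ECV score** — an 8-variable additive points system
(0–13) that predicts whether an external cephalic version (ECV), the manual
procedure that turns a breech or transverse fetus to head-down at term,
will succeed — together with the complete internal-validation toolkit such
a score requires.

The package is for biostatisticians and clinical researchers who want to
compute the score, map it to probabilities, and validate it on their own
cohorts the way prediction-model guidance (TRIPOD) prescribes.

## The score

| factor | condition | points |
|---|---|---|
| parity | multiparous | 2 |
| fetal presentation | transverse / complete breech / frank breech | 2 / 1 / 0 |
| non-engagement of presenting part | yes | 2 |
| palpable fetal head | yes | 2 |
| estimated fetal weight | ≥ 10th percentile | 1 |
| maximum vertical pocket | ≥ 4 cm | 1 |
| placental location | posterior wall | 1 |
| tocolysis before the attempt | yes | 2 |

The weights are prespecified (nothing is refit from data). The total score
`S` maps to a success probability through a univariable logistic model,

```
logit P(success) = a + b·S,
```

fitted by maximum likelihood on a cohort of (score, outcome) records.

## The validation engine

* **Discrimination** — Mann–Whitney AUC with DeLong placement-value
  variance and Wald or bootstrap-percentile confidence intervals.
* **Calibration** — logistic recalibration: the calibration slope is the
  MLE slope of outcome on logit-predictions, the calibration intercept the
  MLE intercept with the logit-predictions as a fixed offset
  (calibration-in-the-large); ideal values (0, 1). Decile bins and a
  LOESS-smoothed curve support calibration plots.
* **Optimism correction** — Harrell's bootstrap: refit in each resample,
  evaluate in-resample and on the original cohort, subtract the mean
  optimism from the apparent metric (2000 resamples by default, seeded,
  degenerate resamples skipped and counted).
* **Clinical utility** — decision-curve net benefit
  `TP/n − FP/n · t/(1−t)` against treat-all/treat-none, Youden-index
  cutoff selection, sensitivity/specificity/PPV/NPV with Wilson score
  intervals, and the prespecified score strata 0–4 / 5–8 / ≥9.
* **Synthetic cohorts** — a Gaussian-copula generator reproducing the
  published predictor prevalences (69% outcome prevalence by default) with
  a latent logistic outcome model, so every analysis is testable without
  patient data. A deterministic 100-patient fixture cohort matching the
  published descriptive table margins ships with the package
  (`published_cohort_fixture()`).

## Worked example

`python examples/03_internal_validation.py` — simulate a 100-patient
cohort at the published scale, fit the score→probability model and
validate it:

```
apparent AUC 0.760 (95% CI 0.655-0.865, DeLong)
           auc: apparent +0.760  corrected +0.760  95% CI [+0.760, +0.760]
 cal_intercept: apparent -0.000  corrected -0.010  95% CI [-0.574, +0.513]
     cal_slope: apparent +1.000  corrected +1.035  95% CI [+0.590, +1.713]
resamples used: 499/500, skipped: {'single_class': 0, 'separation': 0, 'recalibration_failed': 1}
```

Reading the numbers: the score separates successful from failed attempts
moderately well (AUC 0.76 — a random successful case outranks a random
failure 76% of the time). Apparent calibration of a self-fitted model is
the identity (0, 1) by construction; the bootstrap-corrected values and
their percentile intervals show how much of that is optimism. Because the
score is prespecified, AUC optimism is essentially zero — the correction
matters for the calibration intercept and slope.

The other examples score a single patient (`01`), reproduce the
descriptive baseline table (`02`), run decision-curve / cutoff / strata
analyses (`04`), and verify the synthetic generator's fidelity (`05`).

A `preecv` console command exposes the same stages
(`summarize`, `validate`, `dca`, `thresholds`, `simulate`); try
`preecv simulate --n 100 --seed 1 --out cohort.csv` then
`preecv validate cohort.csv --resamples 2000 --seed 1`.

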