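# Methods

## The score and its probability mapping

The PRE-ECV score is a prespecified additive points system over eight
dichotomous/trichotomous predictors assessed immediately before an
external cephalic version attempt (see README for the weight table). The
total `S ∈ {0,…,13}` is mapped to a success probability by a univariable
logistic model `logit P(Y=1) = a + b·S`. Keeping the score's weights fixed
and estimating only `(a, b)` is deliberate: with ~100 patients a refitted
multivariable model would be badly overfit, whereas the two-parameter
mapping is estimable and preserves the prespecified ranking.

The fit is Newton–Raphson (IRLS) with step-halving on any likelihood
decrease, started at `(logit(ȳ), 0)`. Convergence requires the maximum
absolute score-function component < 1e-8 or a parameter change < 1e-10.
Standard errors come from the inverse observed information. Degenerate
inputs are first-class outcomes, not crashes, because the bootstrap
routinely produces them on 100-patient resamples: a single-class resample
raises a degenerate-outcome error, and separation is detected exactly for
the univariable case (classes that do not overlap on the score make the
likelihood monotone in `b`) with two further guards — |b| > 50 (where the
logistic curve is numerically saturated) and non-convergence within 100
iterations. With integer scores, quasi-separated data can satisfy the
score tolerance at |b| ≈ 37–42, so the exact overlap check, not the slope
bound, is the operative detector.

## Discrimination

AUC is computed as the Mann–Whitney statistic (ties at weight 1/2;
identical to trapezoidal ROC area) and is invariant under strictly
increasing transforms of the predictions — in particular, the AUC of the
fitted probabilities equals the AUC of the raw score whenever `b > 0`.
The variance uses DeLong's placement values: `V10_i` is the fraction of
negatives ranked below positive `i` (ties half), `V01_j` symmetric, and
`var = S10/n1 + S01/n0` with sample variances of the placements. The 95%
interval is Wald on the AUC scale truncated to [0, 1]; a logit-scale
variant and a bootstrap-percentile variant are exposed as options because
published reports rarely state which construction they used.

## Calibration

Logistic recalibration regresses the outcome on `logit(p̂)`:

* **calibration slope** — the MLE slope of the joint fit; 1 is ideal,
  < 1 indicates predictions too extreme;
* **calibration intercept** — the MLE intercept when `logit(p̂)` enters as
  a fixed offset (slope pinned at 1), i.e. calibration-in-the-large; 0 is
  ideal. The offset definition is the standard one; the joint-fit
  intercept would be confounded with the slope.

A model evaluated on its own training data satisfies the ML score
equations, so self-recalibration returns exactly (0, 1) — apparent
calibration is always perfect, which is precisely why optimism correction
exists. Calibration plots use equal-count decile bins of the predictions
(ties kept in one bin; unpopulated slots flagged empty) and a LOESS
smoother: degree-1 locally weighted regression with tricube weights over
the `ceil(span·n)` nearest neighbours (span 0.75 by default, no
robustness iterations), evaluated at the sorted distinct predictions and
clipped to [0, 1]. On exactly linear data the local-linear smoother
reproduces the line; at any single point it equals a direct
tricube-weighted least-squares solve, which is how it is tested.

## Bootstrap optimism correction

Harrell's internal validation with simple (unstratified) resampling with
replacement, resample size = cohort size, 2000 resamples by default. Per
resample: refit `(a, b)`, compute each metric in the resample ("boot") and,
using the resample model's predictions on the original cohort, on the
original data ("test"); optimism = boot − test; corrected = apparent −
mean optimism. For the calibration pair the boot value is (0, 1) exactly
(the self-fit identity above), so its optimism reduces to `−test`.
Resamples with one outcome class or separation are skipped — not redrawn,
which would bias the resample distribution — and counted by reason; on
cohorts near the published scale (n = 100, prevalence 0.69) the skip rate
is well under 5%. The generator is a named, seeded `numpy` Generator and
the seed is recorded in the report; a fixed seed makes the whole report
bit-identical.

Two interval constructions are reported per metric: the percentile
interval of the test-performance distribution shifted to the corrected
value (the default `ci95`), and the raw percentile interval of the
per-resample corrected values (`ci95_raw`). Both underlying distributions
are exposed for auditing. Note that for the AUC of a univariable score the
test distribution is nearly degenerate — out-of-sample predictions are a
monotone transform of the same score for every resample with `b > 0` — so
`ci95_raw` is the informative interval for discrimination.

**What optimism correction does and does not do here.** For a
*prespecified* score the ranking of patients never changes when `(a, b)`
are refit, so there is essentially no discrimination optimism to remove:
across simulated cohorts the mean AUC optimism is indistinguishable from
zero (point estimates ~±0.0003 at n = 100, shrinking in magnitude with
n). Likewise, when the data truly follow the latent logistic model the
corrected calibration slope does not exhibit the classic shrinkage below
1 — with no overfitting, `E[b_orig/b_boot] > 1` by Jensen's inequality
slightly *raises* the corrected slope. Substantial corrected-slope
shrinkage on real cohorts therefore signals genuine miscalibration or
model misspecification, not an artifact of the procedure.

## Clinical utility

Net benefit at threshold probability `t` is `TP/n − FP/n · t/(1−t)` with
"treat when `p̂ ≥ t`" (the ≥ convention shifts step locations and is
therefore fixed and documented). Treat-all is
`prevalence − (1−prevalence)·t/(1−t)`, treat-none 0. The default grid is
0.01–0.99 in steps of 0.01; clinically relevant sub-ranges are read off
the full curve, never used to restrict computation. The Youden cutoff
scans every integer cutoff `c` in `[min score, max score + 1]` under the
rule "positive if `S ≥ c`", maximizing `J = sens + spec − 1` with ties
broken toward the larger (more specific) cutoff. All proportions —
sensitivity, specificity, PPV, NPV, and the success rates in the
prespecified strata 0–4 / 5–8 / ≥9 — carry Wilson score intervals; a
zero-denominator metric is reported as undefined, never as 0.

On Wilson coverage: like every binomial interval, the Wilson interval's
exact coverage oscillates with (n, p). At n = 30, p = 0.7 the exact
coverage (sum of binomial probabilities over the covered counts
k = 17…25) is 92.98%, marginally below 93% — close to nominal, but a
reminder that "95%" is an average, not a pointwise guarantee.

## Synthetic cohorts

The generator emulates the published study population: each predictor is
drawn at its published overall prevalence (multiparous 0.55; transverse
0.08 / complete breech 0.16 / frank breech 0.76; non-engaged 0.36;
palpable head 0.69; EFW ≥ 10th pct 0.80; MVP ≥ 4 cm 0.86; posterior
placenta 0.49; tocolysis 0.65), and the outcome is Bernoulli with
`logit P = a + b·S`. Default `b = 0.55` gives 100-patient cohorts with
apparent AUCs broadly in the 0.7–0.8 band — a harness-realism choice, not
an estimate of any real-world effect. When a target prevalence is given
(default 0.69), `a` is solved by bisection so the expected prevalence over
the realized score distribution matches to 1e-6.

Association is injected through a Gaussian copula: the clinically linked
trio — non-engagement, palpable head, adequate fluid — shares a latent
factor giving pairwise correlation ρ (default 0.6, a documented guess);
other predictors are independent. Only the margins of the real cohort are
published, so the joint structure is unknowable; one knob captures the
near-deterministic clustering visible in the published outcome-stratified
counts without pretending to more.

What the generator does **not** emulate: real predictor–outcome pathways
that bypass the score (the outcome depends on predictors only through
`S`), measurement error, operator and temporal effects, and any
miscalibration mechanism. Passing tests on synthetic cohorts therefore
demonstrate the *correctness of the machinery* (estimation, resampling,
intervals), not the clinical performance of the score on new patients.

## The fixture cohort

`published_cohort_fixture()` ships a deterministic 100-record cohort whose
per-predictor-by-outcome counts equal the published descriptive table
(69 successes, 31 failures). Two printed cells are arithmetically
impossible and were resolved: the fetal-presentation column sums (7+11+50
= 68 ≠ 69 successful; 1+5+26 = 32 ≠ 31 unsuccessful) force frank breech
to 51/25 — the unique values preserving both the row totals (8/16/76) and
the column totals; and the palpable-head row's printed percentages are
internally inconsistent, so its counts (69 overall / 63 / 6) are used and
the percentages ignored. The joint arrangement across predictors is not
published; the fixture aligns the engagement-related trio at a common
offset (maximizing their concordance, consistent with the
near-deterministic margins) and staggers the remaining predictors at
distinct deterministic offsets so the score distribution is non-degenerate.
The arrangement is frozen in the packaged CSV and regenerated bit-identically
by the builder it was written with. Margins are faithful; joint structure,
and hence any score-level statistic of the fixture, is one arbitrary
realization — fixture strata rates or cutoffs should not be read as
estimates of the real cohort's.

## Numerical choices and problem sizes

Logistic tolerances as above; recalibration intercept solved by Brent's
method on the score equation in [−50, 50]; prevalence-matching intercept
by bisection in [−60, 60] to 1e-9. Percentages in descriptive summaries
round half-up to one decimal, matching clinical-table convention. The test
suite exercises simulations at n up to 100,000 (marginal checks), a
5,000-patient × 100-replicate coefficient-recovery experiment, and
bootstrap runs of 200–2,000 resamples; these sizes keep Monte-Carlo error
well below the asserted tolerances while the full suite runs in a few
minutes on one CPU.

## Known limitations

* The probability mapping assumes linearity of the log-odds in the score;
  no non-linear (e.g. spline) mapping is provided.
* Lateral/fundal placentas must be dichotomized by the caller to
  "posterior vs not"; the score has no third placental category.
* No handling of missing predictors — absence is a validation error by
  design (imputation is out of scope).
* Internal validation only: there is no external-validation or
  cross-validation machinery, and nothing here can substitute for testing
  the score on independent cohorts.
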