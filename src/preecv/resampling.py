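"""Bootstrap optimism correction of AUC and calibration intercept/slope.

Internal validation by Harrell's optimism bootstrap: the score-to-
probability logistic model is refitted in each resample (simple random
sampling with replacement, resample size = cohort size); each performance
metric is computed within the resample ("boot" performance) and, using the
resample-fitted model's predictions on the original cohort, on the
original data ("test" performance).  The per-resample optimism is
boot - test; the corrected metric is the apparent value minus the mean
optimism.

For the calibration intercept and slope the boot performance is (0, 1)
exactly: a logistic model evaluated on its own training data satisfies the
maximum-likelihood score equations, so recalibration returns the identity.
The optimism of those metrics therefore reduces to (0 - test_intercept,
1 - test_slope).

Resamples with a single outcome class or with (quasi-)separation are
skipped, not redrawn, and counted by reason.  With a fixed seed the whole
report is bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .errors import DegenerateOutcomeError, SeparationError, ValidationError
from .logistic import fit_logistic, predict_prob
from .performance import auc_mann_whitney, recalibrate

__all__ = ["MetricSummary", "OptimismReport", "optimism_correct"]

METRICS = ("auc", "cal_intercept", "cal_slope")


@dataclass(frozen=True)
class MetricSummary:
    apparent: float
    mean_optimism: float
    corrected: float
    #: percentile interval of the test-performance distribution, shifted so
    #: its mean sits at the corrected value
    ci95: tuple[float, float]
    #: raw percentile interval of the per-resample corrected values
    #: (apparent - per-resample optimism)
    ci95_raw: tuple[float, float]
    boot_distribution: np.ndarray = field(repr=False)
    test_distribution: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class OptimismReport:
    n_resamples_requested: int
    n_resamples_used: int
    seed: int
    skipped: dict[str, int]
    metrics: dict[str, MetricSummary]


def _apparent_metrics(x: np.ndarray, y: np.ndarray):
    fit = fit_logistic(x, y)
    preds = predict_prob(fit, x)
    auc = auc_mann_whitney(preds, y)
    cal_int, cal_slope = recalibrate(preds, y)
    return fit, {"auc": auc, "cal_intercept": cal_int, "cal_slope": cal_slope}


def optimism_correct(
    cohort: Cohort,
    n_resamples: int = 2000,
    seed: int = 0,
    *,
    level: float = 0.95,
    identity_resample: bool = False,
) -> OptimismReport:
    """Optimism-corrected AUC, calibration intercept and calibration slope.

    Parameters
    ----------
    cohort : Cohort
        Must contain both outcome classes.
    n_resamples : int
        Bootstrap resamples requested (2000 by default).
    seed : int
        Seed of the named generator; recorded in the report.
    identity_resample : bool
        Diagnostic mode: every "resample" is the original cohort, so boot
        and test performance coincide and every optimism is exactly 0.
    """
    if not isinstance(cohort, Cohort):
        raise ValidationError("optimism_correct expects a Cohort")
    x = cohort.scores().astype(float)
    y = cohort.outcomes().astype(float)
    if y.min() == y.max():
        raise DegenerateOutcomeError("cohort contains a single outcome class")

    _, apparent = _apparent_metrics(x, y)

    rng = np.random.default_rng(seed)
    n = y.size
    boot: dict[str, list[float]] = {m: [] for m in METRICS}
    test: dict[str, list[float]] = {m: [] for m in METRICS}
    skipped = {"single_class": 0, "separation": 0, "recalibration_failed": 0}
    for _ in range(n_resamples):
        idx = np.arange(n) if identity_resample else rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            skipped["single_class"] += 1
            continue
        xb = x[idx]
        try:
            fit_b = fit_logistic(xb, yb)
        except SeparationError:
            skipped["separation"] += 1
            continue
        preds_on_boot = predict_prob(fit_b, xb)
        preds_on_orig = predict_prob(fit_b, x)
        try:
            test_int, test_slope = recalibrate(preds_on_orig, y)
        except (ValidationError, SeparationError, DegenerateOutcomeError):
            skipped["recalibration_failed"] += 1
            continue
        boot["auc"].append(auc_mann_whitney(preds_on_boot, yb))
        test["auc"].append(auc_mann_whitney(preds_on_orig, y))
        # self-fitted calibration is (0, 1) by the MLE score equations
        boot["cal_intercept"].append(0.0)
        boot["cal_slope"].append(1.0)
        test["cal_intercept"].append(test_int)
        test["cal_slope"].append(test_slope)

    n_used = len(boot["auc"])
    if n_used == 0:
        raise DegenerateOutcomeError("every bootstrap resample was degenerate")

    alpha = 1.0 - level
    metrics: dict[str, MetricSummary] = {}
    for m in METRICS:
        b = np.asarray(boot[m])
        t = np.asarray(test[m])
        optimism = b - t
        mean_opt = float(optimism.mean())
        corrected = apparent[m] - mean_opt
        t_lo, t_hi = np.quantile(t, [alpha / 2.0, 1.0 - alpha / 2.0])
        shift = corrected - float(t.mean())
        per_resample_corrected = apparent[m] - optimism
        r_lo, r_hi = np.quantile(
            per_resample_corrected, [alpha / 2.0, 1.0 - alpha / 2.0]
        )
        metrics[m] = MetricSummary(
            apparent=float(apparent[m]),
            mean_optimism=mean_opt,
            corrected=float(corrected),
            ci95=(float(t_lo + shift), float(t_hi + shift)),
            ci95_raw=(float(r_lo), float(r_hi)),
            boot_distribution=b,
            test_distribution=t,
        )
    return OptimismReport(
        n_resamples_requested=n_resamples,
        n_resamples_used=n_used,
        seed=seed,
        skipped=skipped,
        metrics=metrics,
    )
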