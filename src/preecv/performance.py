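"""Discrimination and calibration metrics.

Discrimination is the Mann-Whitney AUC (probability that a random success
outranks a random failure, ties counted 1/2) with its DeLong
placement-value variance and a bootstrap-percentile alternative for the
confidence interval.

Calibration follows the logistic-recalibration framework: the calibration
slope is the MLE slope of a logistic regression of outcomes on the logit
of the predictions, and the calibration intercept (calibration-in-the-
large) is the MLE intercept of the same regression with the logit
predictions entered as a fixed offset.  For a model evaluated on its own
training data these are identically (0, 1) -- apparent calibration is
always perfect, which is why the bootstrap optimism correction in
:mod:`preecv.resampling` exists.  Decile bins and a LOESS-smoothed curve
support calibration plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

from .errors import DegenerateOutcomeError, ValidationError
from .logistic import fit_logistic

__all__ = [
    "AucEstimate",
    "CalibrationBin",
    "CalibrationReport",
    "auc_mann_whitney",
    "delong_ci",
    "recalibrate",
    "calibration_bins",
    "loess_curve",
    "calibration_report",
]


def _check_binary(predictions, outcomes):
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValidationError("predictions and outcomes must be equal-length 1-D")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError("both outcome classes must be present")
    return p, y


def auc_mann_whitney(predictions, outcomes) -> float:
    """AUC as the Mann-Whitney two-sample statistic.

    P(prediction of a random positive > that of a random negative), ties
    counted 1/2; identical to the trapezoidal ROC area.
    """
    p, y = _check_binary(predictions, outcomes)
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = rankdata(p)  # midranks handle ties
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    se_delong: float
    ci95: tuple[float, float]
    method: str  # "delong" or "bootstrap_percentile"


def _placement_values(p: np.ndarray, y: np.ndarray):
    pos = p[y == 1]
    neg = p[y == 0]
    # V10[i] = fraction of negatives ranked below positive i (ties 1/2)
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def delong_ci(
    predictions,
    outcomes,
    level: float = 0.95,
    *,
    method: str = "delong",
    logit_scale: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> AucEstimate:
    """AUC with a confidence interval.

    ``method="delong"`` (default) uses the DeLong placement-value variance
    and a Wald interval, on the AUC scale truncated to [0, 1], or on the
    logit scale when ``logit_scale`` is set.  ``method="bootstrap_percentile"``
    resamples cases with replacement and takes percentile limits; the
    reported standard error is still the DeLong one.
    """
    p, y = _check_binary(predictions, outcomes)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise DegenerateOutcomeError(
            "DeLong variance needs at least 2 members in each class"
        )
    v10, v01 = _placement_values(p, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    se = float(np.sqrt(var))
    z = norm.ppf(0.5 + level / 2.0)
    if method == "delong":
        if logit_scale and 0.0 < auc < 1.0 and se > 0:
            se_logit = se / (auc * (1.0 - auc))
            lo, hi = expit(logit(auc) - z * se_logit), expit(logit(auc) + z * se_logit)
        else:
            lo = max(0.0, auc - z * se)
            hi = min(1.0, auc + z * se)
        return AucEstimate(auc=auc, se_delong=se, ci95=(float(lo), float(hi)), method="delong")
    if method == "bootstrap_percentile":
        rng = np.random.default_rng(seed)
        n = y.size
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            stats.append(auc_mann_whitney(p[idx], yb))
        alpha = 1.0 - level
        lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
        return AucEstimate(
            auc=auc, se_delong=se, ci95=(float(lo), float(hi)),
            method="bootstrap_percentile",
        )
    raise ValidationError(f"unknown CI method {method!r}")


def recalibrate(predictions, outcomes) -> tuple[float, float]:
    """Calibration intercept and slope by logistic recalibration.

    Returns ``(cal_intercept, cal_slope)`` where the slope comes from the
    joint logistic fit of outcomes on logit(predictions) and the intercept
    from the offset model (slope fixed at 1, calibration-in-the-large).
    Predictions must lie strictly in (0, 1) and not all be equal.
    """
    p, y = _check_binary(predictions, outcomes)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValidationError("predictions must lie strictly in (0, 1)")
    lp = logit(p)
    if np.ptp(lp) == 0.0:
        raise ValidationError("constant predictions: calibration slope undefined")
    cal_slope = fit_logistic(lp, y).slope

    def score_eq(a: float) -> float:
        return float(np.sum(y - expit(a + lp)))

    cal_intercept = brentq(score_eq, -50.0, 50.0, xtol=1e-12)
    return float(cal_intercept), float(cal_slope)


@dataclass(frozen=True)
class CalibrationBin:
    mean_predicted: float
    observed_rate: float
    n: int
    empty: bool = False


def calibration_bins(predictions, outcomes, n_bins: int = 10) -> list[CalibrationBin]:
    """Equal-count quantile bins of the predictions (deciles by default).

    Ties are kept together in one bin, so fewer than ``n_bins`` bins may
    be populated; unpopulated slots are returned flagged ``empty`` with
    n = 0.  Bin sizes always sum to the cohort size.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValidationError("predictions and outcomes must be equal-length 1-D")
    if p.size < n_bins:
        raise ValidationError(f"need at least n_bins={n_bins} observations, got {p.size}")
    if np.ptp(p) == 0.0:  # all tied: qcut cannot form any edge
        labels = np.zeros(p.size, dtype=int)
    else:
        labels = pd.qcut(p, n_bins, labels=False, duplicates="drop")
    bins: list[CalibrationBin] = []
    for lab in range(int(labels.max()) + 1):
        mask = labels == lab
        bins.append(
            CalibrationBin(
                mean_predicted=float(p[mask].mean()),
                observed_rate=float(y[mask].mean()),
                n=int(mask.sum()),
            )
        )
    while len(bins) < n_bins:
        bins.append(CalibrationBin(float("nan"), float("nan"), 0, empty=True))
    return bins


def loess_curve(predictions, outcomes, span: float = 0.75) -> list[tuple[float, float]]:
    """LOESS-smoothed calibration curve.

    Locally weighted linear regression (degree 1, tricube weights,
    neighbourhood = the ``ceil(span * n)`` nearest observations) of
    outcome on prediction, evaluated at the sorted distinct observed
    predictions; ordinates clipped to [0, 1].
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValidationError("predictions and outcomes must be equal-length 1-D")
    if p.size < 10:
        raise ValidationError("LOESS needs at least 10 observations")
    if not (0.0 < span <= 1.0):
        raise ValidationError("span must lie in (0, 1]")
    n = p.size
    k = max(2, int(np.ceil(span * n)))
    grid = np.unique(p)
    curve = []
    for x0 in grid:
        curve.append((float(x0), _loess_point(x0, p, y, k)))
    return curve


def _loess_point(x0: float, x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Tricube-weighted degree-1 fit at one evaluation point."""
    d = np.abs(x - x0)
    dk = np.sort(d)[min(k, x.size) - 1]
    if dk == 0.0:
        # all mass at x0: local mean
        return float(np.clip(y[d == 0.0].mean(), 0.0, 1.0))
    w = np.clip(1.0 - (d / dk) ** 3, 0.0, None) ** 3
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0.0:
        yhat = ym
    else:
        slope = (w * (x - xm) * (y - ym)).sum() / sxx
        yhat = ym + slope * (x0 - xm)
    return float(np.clip(yhat, 0.0, 1.0))


@dataclass(frozen=True)
class CalibrationReport:
    cal_intercept: float
    cal_slope: float
    decile_bins: list[CalibrationBin]
    loess_curve: list[tuple[float, float]]


def calibration_report(
    predictions, outcomes, n_bins: int = 10, span: float = 0.75
) -> CalibrationReport:
    """Full calibration summary: recalibration pair, decile bins, LOESS curve."""
    cal_intercept, cal_slope = recalibrate(predictions, outcomes)
    return CalibrationReport(
        cal_intercept=cal_intercept,
        cal_slope=cal_slope,
        decile_bins=calibration_bins(predictions, outcomes, n_bins=n_bins),
        loess_curve=loess_curve(predictions, outcomes, span=span),
    )
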