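"""Clinical-utility tools: decision curves, cutoffs, and stratified rates.

Net benefit at threshold probability t is TP/n - FP/n * t/(1-t), with a
patient "treated" (ECV attempted/expected to succeed) when the predicted
probability is >= t; the treat-all and treat-none policies are the
comparators of decision-curve analysis.  Cutoff selection uses the Youden
index J = sensitivity + specificity - 1 over every integer score cutoff.
All binomial proportions carry Wilson score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigError, DegenerateOutcomeError, ValidationError

__all__ = [
    "DecisionCurve",
    "MetricWithCI",
    "ThresholdReport",
    "Stratum",
    "StrataReport",
    "DEFAULT_STRATA",
    "net_benefit",
    "youden_cutoff",
    "threshold_report",
    "confusion_metrics",
    "wilson_ci",
    "strata_rates",
]

#: Prespecified score strata: 0-4, 5-8 and >=9 points.
DEFAULT_STRATA = ((0, 4), (5, 8), (9, 13))


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Inverts the score test at ``z = Phi^{-1}((1+level)/2)``; the interval
    always contains successes/n and lies inside [0, 1].
    """
    if n <= 0:
        raise ValidationError("wilson_ci needs n > 0")
    if not 0 <= successes <= n:
        raise ValidationError("need 0 <= successes <= n")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
    # the exact Wilson bounds at the boundary counts are 0 and 1; snap away
    # float noise so the interval always contains successes/n
    lo = 0.0 if successes == 0 else float(max(lo, 0.0))
    hi = 1.0 if successes == n else float(min(hi, 1.0))
    return lo, hi


@dataclass(frozen=True)
class MetricWithCI:
    value: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray
    nb_treat_none: np.ndarray


def net_benefit(predictions, outcomes, thresholds=None) -> DecisionCurve:
    """Decision curve of the model against treat-all and treat-none.

    ``thresholds`` defaults to the grid 0.01, 0.02, ..., 0.99; every
    threshold must lie strictly in (0, 1).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValidationError("predictions and outcomes must be equal-length 1-D")
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0, 0.01), 10)
    t = np.asarray(thresholds, dtype=float)
    if np.any(t <= 0.0) or np.any(t >= 1.0):
        raise ValidationError("thresholds must lie strictly in (0, 1)")
    n = y.size
    prevalence = y.mean()
    odds = t / (1.0 - t)
    treated = p[None, :] >= t[:, None]
    tp = (treated & (y[None, :] == 1.0)).sum(axis=1)
    fp = (treated & (y[None, :] == 0.0)).sum(axis=1)
    nb_model = tp / n - fp / n * odds
    nb_all = prevalence - (1.0 - prevalence) * odds
    return DecisionCurve(
        thresholds=t,
        nb_model=nb_model,
        nb_treat_all=nb_all,
        nb_treat_none=np.zeros_like(t),
    )


@dataclass(frozen=True)
class ThresholdReport:
    """Confusion counts and derived metrics at one score cutoff (>= rule)."""

    cutoff: int
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: MetricWithCI | None
    specificity: MetricWithCI | None
    ppv: MetricWithCI | None
    npv: MetricWithCI | None
    youden_j: float


def confusion_metrics(tp: int, fp: int, fn: int, tn: int, level: float = 0.95):
    """Sensitivity, specificity, PPV and NPV with Wilson CIs.

    Returns a dict metric-name -> :class:`MetricWithCI`, with ``None`` for
    any metric whose denominator is zero (undefined, never reported as 0).
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0 or int(v) != v:
            raise ValidationError(f"count {name} must be a non-negative integer")
    out: dict[str, MetricWithCI | None] = {}
    for name, num, denom in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        if denom == 0:
            out[name] = None
        else:
            out[name] = MetricWithCI(
                value=num / denom, ci95=wilson_ci(num, denom, level=level)
            )
    return out


def threshold_report(scores, outcomes, cutoff: int, level: float = 0.95) -> ThresholdReport:
    """Evaluate the rule "positive if score >= cutoff" on a cohort."""
    x = np.asarray(scores)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("scores and outcomes must be equal-length 1-D")
    pos = x >= cutoff
    tp = int(np.sum(pos & (y == 1.0)))
    fp = int(np.sum(pos & (y == 0.0)))
    fn = int(np.sum(~pos & (y == 1.0)))
    tn = int(np.sum(~pos & (y == 0.0)))
    m = confusion_metrics(tp, fp, fn, tn, level=level)
    sens = m["sensitivity"].value if m["sensitivity"] else float("nan")
    spec = m["specificity"].value if m["specificity"] else float("nan")
    return ThresholdReport(
        cutoff=int(cutoff),
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        ppv=m["ppv"],
        npv=m["npv"],
        youden_j=sens + spec - 1.0,
    )


def youden_cutoff(scores, outcomes, level: float = 0.95) -> ThresholdReport:
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    Every integer cutoff c in [min score, max score + 1] is evaluated with
    the rule "positive if score >= c"; ties are broken toward the largest
    cutoff (the more specific rule).
    """
    x = np.asarray(scores)
    y = np.asarray(outcomes, dtype=float)
    if y.min() == y.max():
        raise DegenerateOutcomeError("both outcome classes must be present")
    best: ThresholdReport | None = None
    for c in range(int(x.min()), int(x.max()) + 2):
        rep = threshold_report(x, y, c, level=level)
        if best is None or rep.youden_j >= best.youden_j - 1e-12:
            best = rep
    return best


@dataclass(frozen=True)
class Stratum:
    label: str
    lo: int
    hi: int
    n: int
    successes: int
    rate: float  # nan when n = 0
    ci95: tuple[float, float] | None  # None when n = 0


@dataclass(frozen=True)
class StrataReport:
    strata: tuple[Stratum, ...]


def strata_rates(scores, outcomes, strata=DEFAULT_STRATA, level: float = 0.95) -> StrataReport:
    """Observed success rate with Wilson CI in each prespecified stratum.

    ``strata`` is an ordered sequence of inclusive integer (lo, hi) bands
    that must be contiguous and non-overlapping and must cover every
    observed score; empty strata are reported with n = 0 and an undefined
    rate.
    """
    x = np.asarray(scores)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("scores and outcomes must be equal-length 1-D")
    bands = [(int(lo), int(hi)) for lo, hi in strata]
    for lo, hi in bands:
        if lo > hi:
            raise ConfigError(f"stratum ({lo}, {hi}) has lo > hi")
    for (_, hi1), (lo2, _) in zip(bands, bands[1:]):
        if lo2 != hi1 + 1:
            raise ConfigError(
                f"strata must be contiguous and non-overlapping; gap/overlap "
                f"between hi={hi1} and lo={lo2}"
            )
    if x.min() < bands[0][0] or x.max() > bands[-1][1]:
        raise ConfigError(
            f"strata [{bands[0][0]}, {bands[-1][1]}] do not cover the observed "
            f"score range [{x.min()}, {x.max()}]"
        )
    out = []
    for i, (lo, hi) in enumerate(bands):
        mask = (x >= lo) & (x <= hi)
        n = int(mask.sum())
        k = int(y[mask].sum())
        label = f"{lo}-{hi}" if i < len(bands) - 1 else f">={lo}"
        out.append(
            Stratum(
                label=label, lo=lo, hi=hi, n=n, successes=k,
                rate=k / n if n else float("nan"),
                ci95=wilson_ci(k, n, level=level) if n else None,
            )
        )
    return StrataReport(strata=tuple(out))
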