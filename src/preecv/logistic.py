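"""Univariable logistic model mapping the total score to success probability.

The score-to-probability map is deliberately a one-predictor logistic
regression, ``logit P(success) = a + b * score``, fitted by maximum
likelihood.  The fit is Newton-Raphson (equivalently IRLS) with
step-halving on likelihood decrease, started at ``(logit(mean y), 0)``.

Convergence: max absolute score-function component < 1e-8, or parameter
change < 1e-10.  Perfect or quasi-separation -- a monotone likelihood,
which occurs routinely on small bootstrap resamples -- is detected as a
divergent slope (|b| > 50, where the logistic curve is numerically
saturated) or non-convergence within 100 iterations, and raised as
:class:`SeparationError` so resampling code can skip and count it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .errors import DegenerateOutcomeError, PreEcvError, SeparationError, ValidationError

__all__ = ["LogisticFit", "fit_logistic", "predict_prob"]

_MAX_ITER = 100
_SCORE_TOL = 1e-8
_PARAM_TOL = 1e-10
_SLOPE_DIVERGENCE = 50.0


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood intercept/slope with fit diagnostics.

    ``intercept`` is the log-odds of success at score 0; ``slope`` the
    log-odds increment per score point.  Standard errors come from the
    inverse observed information at the MLE.
    """

    intercept: float
    slope: float
    converged: bool
    log_likelihood: float
    se_intercept: float
    se_slope: float
    n_iterations: int


def _log_likelihood(a: float, b: float, x: np.ndarray, y: np.ndarray) -> float:
    eta = a + b * x
    # log(1 + e^eta) computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(scores, outcomes) -> LogisticFit:
    """Fit ``logit P(y=1) = a + b * score`` by Newton-Raphson MLE.

    Parameters
    ----------
    scores : sequence of numbers (the integer totals, but any reals work)
    outcomes : sequence of 0/1

    Raises
    ------
    DegenerateOutcomeError
        If all outcomes are the same class.
    SeparationError
        On perfect/quasi-separation (divergent slope or non-convergence).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValidationError("scores and outcomes must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError("all outcomes are the same class; model undefined")
    # exact check for one predictor: non-overlapping classes make the
    # likelihood monotone in the slope (perfect separation)
    if x[y == 0].max() < x[y == 1].min() or x[y == 1].max() < x[y == 0].min():
        raise SeparationError("classes are perfectly separated by the score")

    theta = np.array([logit(y.mean()), 0.0])
    ll = _log_likelihood(theta[0], theta[1], x, y)
    X = np.column_stack([np.ones_like(x), x])
    n_iter = 0
    converged = False
    for n_iter in range(1, _MAX_ITER + 1):
        p = expit(X @ theta)
        grad = X.T @ (y - p)  # score function
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])  # observed information
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix (separation or constant scores)"
            ) from None
        # step-halving: never accept a likelihood decrease
        lam = 1.0
        for _ in range(30):
            cand = theta + lam * step
            ll_cand = _log_likelihood(cand[0], cand[1], x, y)
            if ll_cand >= ll - 1e-12:
                break
            lam /= 2.0
        theta_new, ll = cand, ll_cand
        delta = np.max(np.abs(theta_new - theta))
        theta = theta_new
        if abs(theta[1]) > _SLOPE_DIVERGENCE:
            raise SeparationError(
                f"|slope| exceeded {_SLOPE_DIVERGENCE}; data are (quasi-)separated"
            )
        if np.max(np.abs(grad)) < _SCORE_TOL or delta < _PARAM_TOL:
            converged = True
            break
    if not converged:
        raise SeparationError(f"no convergence in {_MAX_ITER} iterations")

    p = expit(X @ theta)
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    return LogisticFit(
        intercept=float(theta[0]),
        slope=float(theta[1]),
        converged=True,
        log_likelihood=ll,
        se_intercept=float(np.sqrt(cov[0, 0])),
        se_slope=float(np.sqrt(cov[1, 1])),
        n_iterations=n_iter,
    )


def predict_prob(fit: LogisticFit, score) -> float | np.ndarray:
    """Predicted success probability at one or many scores.

    ``inverse-logit(intercept + slope * score)``; strictly inside (0, 1)
    and monotone increasing in score when the slope is positive.
    """
    if not isinstance(fit, LogisticFit):
        raise ValidationError("predict_prob expects a LogisticFit")
    if not fit.converged:
        raise PreEcvError("cannot predict from a non-converged fit")
    out = expit(fit.intercept + fit.slope * np.asarray(score, dtype=float))
    return float(out) if np.ndim(score) == 0 else out
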