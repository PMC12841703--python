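"""AUC, DeLong variance, recalibration, decile bins, LOESS — each checked
against an independent route (pair counting, bootstrap, refits, direct WLS)."""

import numpy as np
import pytest
from scipy.special import expit, logit

from preecv import (
    DegenerateOutcomeError,
    ValidationError,
    auc_mann_whitney,
    calibration_bins,
    calibration_report,
    delong_ci,
    fit_logistic,
    loess_curve,
    predict_prob,
    recalibrate,
)
from conftest import random_binary_dataset


def _pair_counting_auc(preds, y):
    """Exhaustive oracle: count concordant pos/neg pairs, ties 1/2."""
    preds = np.asarray(preds, float)
    y = np.asarray(y)
    pos = preds[y == 1]
    neg = preds[y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_mann_whitney([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_is_half(self):
        assert auc_mann_whitney([0.4] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_four_point_example(self):
        # positives {0.35, 0.8} vs negatives {0.1, 0.4}: 3 of 4 pairs concordant
        preds = [0.1, 0.4, 0.35, 0.8]
        y = [0, 0, 1, 1]
        assert auc_mann_whitney(preds, y) == pytest.approx(0.75)
        assert auc_mann_whitney(preds, y) == pytest.approx(_pair_counting_auc(preds, y))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        preds, y = random_binary_dataset(rng, n)
        preds = np.round(preds, 1)  # force some ties
        assert auc_mann_whitney(preds, y) == pytest.approx(
            _pair_counting_auc(preds, y), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        preds, y = random_binary_dataset(rng, 40)
        base = auc_mann_whitney(preds, y)
        for f in (lambda p: 3 * p + 1, np.exp, lambda p: p**3):
            assert auc_mann_whitney(f(preds), y) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            auc_mann_whitney([0.2, 0.4], [1, 1])


class TestDeLong:
    def test_perfect_separation_zero_variance(self):
        est = delong_ci([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert est.auc == 1.0
        assert est.se_delong == 0.0
        assert est.ci95 == (1.0, 1.0)

    def test_symmetric_data_centered_ci(self):
        # AUC exactly 0.5 by symmetry: CI symmetric about the point estimate
        preds = [0.1, 0.2, 0.3, 0.4, 0.1, 0.2, 0.3, 0.4]
        y = [0, 0, 1, 1, 1, 1, 0, 0]
        est = delong_ci(preds, y)
        assert est.auc == pytest.approx(0.5)
        assert est.ci95[0] + est.ci95[1] == pytest.approx(1.0)

    def test_se_close_to_bootstrap_oracle(self):
        rng = np.random.default_rng(5)
        preds, y = random_binary_dataset(rng, 40)
        est = delong_ci(preds, y)
        boot = []
        for _ in range(10_000):
            idx = rng.integers(0, 40, 40)
            if y[idx].min() == y[idx].max():
                continue
            boot.append(auc_mann_whitney(preds[idx], y[idx]))
        se_boot = np.std(boot, ddof=1)
        assert est.se_delong == pytest.approx(se_boot, rel=0.15)

    def test_bootstrap_percentile_variant(self):
        rng = np.random.default_rng(3)
        preds, y = random_binary_dataset(rng, 60)
        est = delong_ci(preds, y, method="bootstrap_percentile", n_boot=500, seed=1)
        assert est.method == "bootstrap_percentile"
        assert est.ci95[0] <= est.auc <= est.ci95[1]

    def test_logit_scale_ci_inside_unit_interval(self):
        rng = np.random.default_rng(9)
        preds, y = random_binary_dataset(rng, 30)
        est = delong_ci(preds, y, logit_scale=True)
        assert 0.0 < est.ci95[0] < est.ci95[1] < 1.0

    def test_small_class_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            delong_ci([0.1, 0.9, 0.5], [0, 1, 0])


class TestRecalibrate:
    def test_self_fitted_is_identity(self, fixture_cohort):
        x, y = fixture_cohort.scores(), fixture_cohort.outcomes()
        fit = fit_logistic(x, y)
        preds = predict_prob(fit, x)
        cal_int, cal_slope = recalibrate(preds, y)
        assert cal_int == pytest.approx(0.0, abs=1e-6)
        assert cal_slope == pytest.approx(1.0, abs=1e-6)

    def test_doubling_logit_halves_slope(self, fixture_cohort):
        x, y = fixture_cohort.scores(), fixture_cohort.outcomes()
        preds = predict_prob(fit_logistic(x, y), x)
        _, slope1 = recalibrate(preds, y)
        doubled = expit(2.0 * logit(preds))
        _, slope2 = recalibrate(doubled, y)
        assert slope2 == pytest.approx(slope1 / 2.0, rel=1e-9)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValidationError):
            recalibrate([0.4] * 10, [0, 1] * 5)

    def test_boundary_predictions_rejected(self):
        with pytest.raises(ValidationError):
            recalibrate([0.0, 0.5, 0.9, 0.2], [0, 1, 1, 0])


class TestCalibrationBins:
    def test_equal_sizes_without_ties(self):
        rng = np.random.default_rng(2)
        preds = rng.permutation(np.linspace(0.01, 0.99, 100))
        y = (rng.random(100) < preds).astype(int)
        bins = calibration_bins(preds, y, n_bins=10)
        assert [b.n for b in bins] == [10] * 10
        assert sum(b.n for b in bins) == 100

    def test_wellcalibrated_simulation(self):
        rng = np.random.default_rng(8)
        n = 20_000
        preds = rng.uniform(0.05, 0.95, n)
        y = (rng.random(n) < preds).astype(int)
        for b in calibration_bins(preds, y):
            se = np.sqrt(b.mean_predicted * (1 - b.mean_predicted) / b.n)
            assert abs(b.observed_rate - b.mean_predicted) < 3 * se

    def test_all_tied_single_effective_bin(self):
        bins = calibration_bins([0.3] * 20, [0, 1] * 10, n_bins=10)
        assert bins[0].n == 20
        assert bins[0].observed_rate == 0.5
        assert all(b.empty and b.n == 0 for b in bins[1:])

    def test_too_few_observations(self):
        with pytest.raises(ValidationError):
            calibration_bins([0.1, 0.5, 0.9], [0, 1, 1], n_bins=10)


def _wls_tricube_point(x0, x, y, span):
    """Direct single-point oracle: tricube-weighted degree-1 least squares."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    k = max(2, int(np.ceil(span * x.size)))
    d = np.abs(x - x0)
    dk = np.sort(d)[k - 1]
    w = np.clip(1 - (d / dk) ** 3, 0, None) ** 3
    X = np.column_stack([np.ones_like(x), x - x0])
    beta, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None)
    return float(np.clip(beta[0], 0.0, 1.0))


class TestLoess:
    def test_reproduces_linear_data(self):
        x = np.linspace(0.1, 0.9, 25)
        y = 0.2 + 0.6 * x  # inside [0,1], no clipping
        curve = loess_curve(x, y, span=0.5)
        for cx, cy in curve[3:-3]:
            assert cy == pytest.approx(0.2 + 0.6 * cx, abs=1e-6)

    def test_constant_outcomes_constant_curve(self):
        x = np.linspace(0, 1, 15)
        curve = loess_curve(x, np.full(15, 1.0))
        assert all(cy == pytest.approx(1.0) for _, cy in curve)

    def test_matches_direct_wls_oracle(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.random(14))
        y = (rng.random(14) < x).astype(float)
        span = 0.75
        curve = dict(loess_curve(x, y, span=span))
        for x0 in list(curve)[2:-2]:
            assert curve[x0] == pytest.approx(
                _wls_tricube_point(x0, x, y, span), abs=1e-9
            )

    def test_ordinates_clipped(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.random(30))
        y = rng.integers(0, 2, 30).astype(float)
        assert all(0.0 <= cy <= 1.0 for _, cy in loess_curve(x, y, span=0.3))

    def test_span_validation(self):
        x = np.linspace(0, 1, 12)
        with pytest.raises(ValidationError):
            loess_curve(x, x, span=0.0)
        with pytest.raises(ValidationError):
            loess_curve(x, x, span=1.5)

    def test_needs_ten_observations(self):
        with pytest.raises(ValidationError):
            loess_curve([0.1] * 5, [1] * 5)


def test_calibration_report_assembles(fixture_cohort):
    x, y = fixture_cohort.scores(), fixture_cohort.outcomes()
    preds = predict_prob(fit_logistic(x, y), x)
    rep = calibration_report(preds, y)
    assert rep.cal_intercept == pytest.approx(0.0, abs=1e-6)
    assert rep.cal_slope == pytest.approx(1.0, abs=1e-6)
    assert sum(b.n for b in rep.decile_bins) == len(fixture_cohort)
    assert all(0.0 <= cy <= 1.0 for _, cy in rep.loess_curve)
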