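"""Evaluation-suite tests: metrics, coverage curves, CV selection, ablation plumbing."""

import numpy as np
import pytest
from scipy.stats import norm

from ramanuq import (
    CVPlan,
    ConformalAdjustment,
    PredictionInterval,
    accuracy_metrics,
    coverage_curve,
    cross_validate,
    empirical_coverage,
    uncertainty_metrics,
)
from ramanuq.evaluate import _lower_median_index, plot_calibration_curve
from ramanuq.experiments import LinearSOCModel


def _intervals(lowers, uppers):
    return [PredictionInterval(lo, up, 0.9) for lo, up in zip(lowers, uppers)]


class TestEmpiricalCoverage:
    def test_counting(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        ivs = _intervals([0, 1.5, 2.5, 4.0], [2, 2.5, 3.5, 4.5])
        assert empirical_coverage(y, ivs) == pytest.approx(0.75 + 0.25)  # boundary covered

    def test_all_inside_and_all_outside(self):
        y = np.array([1.0, 2.0])
        assert empirical_coverage(y, _intervals([0, 0], [5, 5])) == 1.0
        assert empirical_coverage(y, _intervals([5, 5], [6, 6])) == 0.0

    def test_nine_of_ten(self):
        y = np.arange(10.0)
        lowers = y - 0.5
        uppers = y + 0.5
        uppers[3] = y[3] - 0.2  # push one value outside
        lowers[3] = y[3] - 0.4
        assert empirical_coverage(y, _intervals(lowers, uppers)) == pytest.approx(0.9)

    def test_order_invariance(self, rng):
        y = rng.normal(size=30)
        lowers, uppers = y - rng.uniform(0, 1, 30), y + rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        assert empirical_coverage(y, _intervals(lowers, uppers)) == pytest.approx(
            empirical_coverage(y[perm], _intervals(lowers[perm], uppers[perm]))
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_coverage(np.array([]), [])


class TestAccuracyMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = accuracy_metrics(y, y)
        assert m == {"r2": 1.0, "mae": 0.0, "mape": 0.0, "rmse": 0.0}

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = accuracy_metrics(y, np.full(4, y.mean()))
        assert m["r2"] == pytest.approx(0.0)

    def test_three_point_hand_case(self):
        y = np.array([1.0, 2.0, 4.0])
        pred = np.array([1.5, 2.0, 3.0])
        m = accuracy_metrics(y, pred)
        assert m["mae"] == pytest.approx(0.5)
        assert m["rmse"] == pytest.approx(np.sqrt((0.25 + 0 + 1) / 3))
        assert m["mape"] == pytest.approx((0.5 / 1 + 0 + 1 / 4) / 3 * 100)
        sstot = ((y - y.mean()) ** 2).sum()
        assert m["r2"] == pytest.approx(1 - 1.25 / sstot)

    def test_zero_truth_rejected_for_mape(self):
        with pytest.raises(ValueError, match="MAPE"):
            accuracy_metrics(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestUncertaintyMetrics:
    def test_constant_sigma_flagged(self):
        y = np.array([1.0, 2.0, 3.0])
        sharp, consist, info = uncertainty_metrics(y, y + 0.1, np.full(3, 0.7))
        assert sharp == pytest.approx(0.7)
        assert consist == pytest.approx(0.0)
        assert info is None

    def test_sigma_equal_to_error_fully_informative(self, rng):
        y = rng.normal(size=50)
        pred = y + rng.normal(size=50) * 0.3
        _, _, info = uncertainty_metrics(y, pred, np.abs(y - pred))
        assert info == pytest.approx(1.0)

    def test_four_point_hand_case(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.8, 3.4, 4.0])
        sigma = np.array([0.2, 0.1, 0.5, 0.3])
        sharp, consist, info = uncertainty_metrics(y, pred, sigma)
        assert sharp == pytest.approx(np.median(sigma))
        assert consist == pytest.approx(np.var(sigma))
        abs_err = np.abs(y - pred)
        expected = np.corrcoef(abs_err, sigma)[0, 1]
        assert info == pytest.approx(expected)


class TestCoverageCurve:
    def test_gaussian_residuals_with_true_sigma_are_calibrated(self, rng):
        """Known sigma + Gaussian noise: calibration RMSE -> 0 at large n."""
        n = 5000
        sigma = rng.uniform(0.3, 1.2, size=n)
        y_hat = rng.normal(size=n)
        y = y_hat + rng.normal(size=n) * sigma
        report = coverage_curve(y, y_hat, sigma)
        assert report.calibration_rmse <= 0.03
        assert abs(report.coverage_by_level[0.9] - 0.9) <= 0.02

    def test_degenerate_zero_sigma_covers_nothing(self, rng):
        y_hat = rng.normal(size=50)
        y = y_hat + 0.1
        report = coverage_curve(y, y_hat, np.zeros(50))
        assert all(v == 0.0 for v in report.coverage_by_level.values())

    def test_conformal_adjustment_changes_ninety_level(self, rng):
        n = 400
        y_hat = rng.normal(size=n)
        y = y_hat + rng.normal(size=n)  # true sigma 1
        sigma_hat = np.full(n, 0.5)  # under-scaled by half
        before = coverage_curve(y, y_hat, sigma_hat)
        adj = ConformalAdjustment(
            alpha=0.1, z=norm.ppf(0.95),
            scores=np.abs(rng.normal(size=100)) - norm.ppf(0.95) * 0.5,
            q_hat=0.0,
        )
        adj.q_hat = np.sort(adj.scores)[90]
        after = coverage_curve(y, y_hat, sigma_hat, adj)
        assert before.coverage_by_level[0.9] < 0.75
        assert after.coverage_by_level[0.9] > before.coverage_by_level[0.9]
        assert after.calibration_rmse < before.calibration_rmse

    def test_invalid_level_rejected(self, rng):
        with pytest.raises(ValueError, match="level"):
            coverage_curve(rng.normal(size=5), np.zeros(5), np.ones(5), levels=[1.5])

    def test_json_and_plot_writers(self, tmp_path, rng):
        y_hat = rng.normal(size=100)
        y = y_hat + rng.normal(size=100) * 0.5
        rep = coverage_curve(y, y_hat, np.full(100, 0.5))
        out = rep.to_json(tmp_path / "rep.json")
        assert "coverage_by_level" in out
        path = plot_calibration_curve({"demo": rep}, tmp_path / "curve.png")
        assert path.exists()


class TestCrossValidation:
    def test_median_selection_rule(self):
        assert _lower_median_index([0.01, 0.03, 0.08]) == 1
        assert _lower_median_index([0.08, 0.01, 0.03]) == 2  # index of 0.03
        assert _lower_median_index([0.4, 0.1, 0.3, 0.2]) == 3  # lower median of 4

    def _dataset(self, rng, n=120, d=6):
        X = rng.normal(size=(n, d))
        y = 3.0 + X[:, 0] + 0.3 * rng.normal(size=n)
        return X, y

    def test_every_sample_predicted_exactly_once(self, rng):
        X, y = self._dataset(rng)
        plan = CVPlan(n_folds=4, n_repeats_per_fold=3, calibration_size=20, seed=1)
        result = cross_validate(X, y, lambda s: LinearSOCModel(), plan)
        assert not np.any(np.isnan(result.y_hat))
        assert result.y_hat.shape == y.shape
        assert len(result.fold_reports) == 4
        assert len(result.selected_coverage_errors) == 4

    def test_seeded_run_is_reproducible(self, rng):
        X, y = self._dataset(rng)
        plan = CVPlan(n_folds=3, n_repeats_per_fold=2, calibration_size=15, seed=5)
        a = cross_validate(X, y, lambda s: LinearSOCModel(), plan)
        b = cross_validate(X, y, lambda s: LinearSOCModel(), plan)
        np.testing.assert_array_equal(a.y_hat, b.y_hat)
        np.testing.assert_array_equal(a.sigma_cal, b.sigma_cal)

    def test_infeasible_calibration_size_rejected(self, rng):
        X, y = self._dataset(rng, n=60)
        plan = CVPlan(n_folds=3, n_repeats_per_fold=2, calibration_size=50, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            cross_validate(X, y, lambda s: LinearSOCModel(), plan)
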