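"""Split-conformal calibration tests against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanuq import (
    ConformalAdjustment,
    UQPrediction,
    calibrate,
    calibrate_from_records,
    calibrated_sigma,
    conformal_quantile,
    default_z,
    nonconformity_score,
    predict_interval,
)
from ramanuq.conformal import CalibrationRecord


def brute_force_quantile(scores, alpha):
    """Independent oracle: sort and index, k = ceil((n+1)(1-alpha))."""
    s = sorted(scores)
    k = math.ceil((len(s) + 1) * (1 - alpha))
    return s[k - 1] if k <= len(s) else math.inf


class _FixedModel:
    """Deterministic stub: y_hat = first feature, sigma_hat constant."""

    def __init__(self, sigma=0.5, bias=0.0):
        self.sigma = sigma
        self.bias = bias

    def predict(self, X):
        X = np.atleast_2d(X)
        mu = X[:, 0] + self.bias
        return mu, np.full_like(mu, self.sigma)


class TestNonconformityScore:
    def test_center_of_zero_width_interval(self):
        assert nonconformity_score(2.0, UQPrediction(2.0, 0.0), 1.64) == 0.0

    def test_inside_interval_is_negative(self):
        s = nonconformity_score(2.0, UQPrediction(2.0, 0.5), 1.64)
        assert s == pytest.approx(-0.82)

    def test_outside_interval_is_positive(self):
        s = nonconformity_score(4.0, UQPrediction(2.0, 0.5), 1.64)
        assert s == pytest.approx(1.18)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            nonconformity_score(float("nan"), UQPrediction(2.0, 0.5), 1.64)


class TestConformalQuantile:
    def test_all_equal_scores(self):
        assert conformal_quantile([3.0] * 25, 0.1) == 3.0

    def test_sort_and_index_example(self):
        assert conformal_quantile(np.arange(1.0, 20.0), 0.1) == 18.0

    def test_small_n_returns_infinity_sentinel(self):
        assert conformal_quantile([1.0, 2.0, 3.0], 0.1) == math.inf

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            conformal_quantile([], 0.1)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 51))
            scores = rng.normal(size=n) * rng.uniform(0.1, 10)
            alpha = float(rng.uniform(0.01, 0.99))
            assert conformal_quantile(scores, alpha) == brute_force_quantile(scores, alpha)

    @given(st.integers(1, 60), st.floats(0.01, 0.5), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_as_alpha_decreases(self, n, alpha, seed):
        scores = np.random.default_rng(seed).normal(size=n)
        lo = conformal_quantile(scores, alpha)
        hi = conformal_quantile(scores, alpha / 2)
        assert hi >= lo


class TestCalibrate:
    def test_perfect_model_gives_negative_qhat(self):
        model = _FixedModel(sigma=0.5)
        X = np.linspace(1, 5, 40)[:, None]
        adj = calibrate(model, X, X[:, 0], alpha=0.1, z=1.64)
        np.testing.assert_allclose(adj.scores, -0.82)
        assert adj.q_hat == pytest.approx(-0.82)

    def test_qhat_is_91st_smallest_of_100(self, rng):
        model = _FixedModel(sigma=0.3)
        X = rng.normal(size=(100, 1))
        y = X[:, 0] + rng.normal(size=100)
        adj = calibrate(model, X, y, alpha=0.1)
        assert adj.n == 100
        assert adj.q_hat == np.sort(adj.scores)[90]

    def test_infinite_sentinel_propagates_to_interval(self):
        model = _FixedModel()
        X = np.ones((3, 1))
        adj = calibrate(model, X, X[:, 0], alpha=0.1)
        assert adj.q_hat == math.inf
        iv = predict_interval(UQPrediction(2.0, 0.5), adj)
        assert iv.lower == -math.inf and iv.upper == math.inf

    def test_empty_calibration_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate(_FixedModel(), np.empty((0, 1)), np.empty(0))

    def test_records_variant_agrees(self, rng):
        model = _FixedModel(sigma=0.4)
        X = rng.normal(size=(30, 1))
        y = X[:, 0] + rng.normal(size=30) * 0.3
        adj = calibrate(model, X, y, alpha=0.2)
        mu, sig = model.predict(X)
        records = [
            CalibrationRecord(x, yy, UQPrediction(m, s))
            for x, yy, m, s in zip(X, y, mu, sig)
        ]
        adj2 = calibrate_from_records(records, alpha=0.2)
        assert adj2.q_hat == pytest.approx(adj.q_hat)


class TestIntervalAndSigma:
    adj = ConformalAdjustment(alpha=0.1, z=1.64, scores=np.zeros(50), q_hat=0.2)

    def test_interval_arithmetic(self):
        iv = predict_interval(UQPrediction(3.0, 0.5), self.adj)
        assert iv.lower == pytest.approx(1.98)
        assert iv.upper == pytest.approx(4.02)

    def test_zero_qhat_reduces_to_uncalibrated(self):
        adj = ConformalAdjustment(alpha=0.1, z=1.64, scores=np.zeros(50), q_hat=0.0)
        iv = predict_interval(UQPrediction(3.0, 0.5), adj)
        assert iv.lower == pytest.approx(3.0 - 1.64 * 0.5)
        assert iv.upper == pytest.approx(3.0 + 1.64 * 0.5)

    def test_calibrated_sigma_arithmetic(self):
        adj = ConformalAdjustment(alpha=0.1, z=1.64, scores=np.zeros(50), q_hat=0.164)
        assert calibrated_sigma(UQPrediction(3.0, 0.5), adj) == pytest.approx(0.6)

    def test_zero_qhat_keeps_sigma(self):
        adj = ConformalAdjustment(alpha=0.1, z=1.64, scores=np.zeros(50), q_hat=0.0)
        assert calibrated_sigma(UQPrediction(3.0, 0.5), adj) == pytest.approx(0.5)

    def test_negative_sigma_clamped_with_warning(self, caplog):
        adj = ConformalAdjustment(alpha=0.1, z=1.64, scores=np.zeros(50), q_hat=-2.0)
        with caplog.at_level("WARNING", logger="ramanuq.conformal"):
            out = calibrated_sigma(UQPrediction(3.0, 0.1), adj)
        assert out == 0.0
        assert "clamping" in caplog.text

    def test_rebuilt_90_interval_identical_to_conformal_interval(self, rng):
        for _ in range(50):
            pred = UQPrediction(float(rng.normal()), float(rng.uniform(0.1, 2)))
            q = float(rng.uniform(-0.1, 1.0))
            adj = ConformalAdjustment(alpha=0.1, z=default_z(0.1), scores=np.zeros(20),
                                      q_hat=q)
            sigma = calibrated_sigma(pred, adj)
            iv = predict_interval(pred, adj)
            assert pred.y_hat - adj.z * sigma == pytest.approx(iv.lower, abs=1e-12)
            assert pred.y_hat + adj.z * sigma == pytest.approx(iv.upper, abs=1e-12)

    def test_duality_membership_iff_score_below_qhat(self, rng):
        """y in C(x) exactly when s(x, y) <= q_hat, over a dense y grid."""
        for _ in range(20):
            pred = UQPrediction(float(rng.normal()), float(rng.uniform(0, 1.5)))
            q = float(rng.uniform(-0.3, 1.0))
            adj = ConformalAdjustment(alpha=0.1, z=1.6449, scores=np.zeros(30), q_hat=q)
            iv = predict_interval(pred, adj)
            for y in np.linspace(pred.y_hat - 5, pred.y_hat + 5, 201):
                inside = iv.lower <= y <= iv.upper
                assert inside == (nonconformity_score(y, pred, adj.z) <= q + 1e-12)

    def test_width_constant_in_y_and_increasing_in_sigma(self):
        widths = [
            predict_interval(UQPrediction(0.0, s), self.adj).width for s in (0.1, 0.5, 1.0)
        ]
        assert widths == sorted(widths)
        same = predict_interval(UQPrediction(42.0, 0.5), self.adj).width
        assert same == pytest.approx(predict_interval(UQPrediction(-3.0, 0.5), self.adj).width)


class TestDefaults:
    def test_default_z_is_normal_95th_percentile(self):
        assert round(default_z(0.1), 2) == 1.64
        assert default_z(0.1) == pytest.approx(1.6449, abs=1e-4)

    def test_json_round_trip(self, tmp_path, rng):
        adj = ConformalAdjustment(alpha=0.1, z=1.6449, scores=rng.normal(size=20),
                                  q_hat=0.33)
        path = tmp_path / "adj.json"
        adj.to_json(path, model_ref="ckpt")
        back = ConformalAdjustment.from_json(path)
        assert back.alpha == adj.alpha
        assert back.q_hat == pytest.approx(adj.q_hat)
        np.testing.assert_allclose(back.scores, adj.scores)

    def test_json_round_trip_with_sentinel(self, tmp_path):
        adj = ConformalAdjustment(alpha=0.1, z=1.64, scores=np.array([1.0, 2.0]),
                                  q_hat=math.inf)
        path = tmp_path / "adj.json"
        adj.to_json(path)
        assert ConformalAdjustment.from_json(path).q_hat == math.inf
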