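"""Split-conformal calibration of heuristic (yhat, sigma-hat) predictors.

Any model exposing ``predict(X) -> (yhat, sigma_hat)`` can be calibrated on a
held-out set so that 90% (or any 1-alpha) prediction intervals attain valid
marginal coverage regardless of how miscalibrated the raw sigma-hat is.

The construction: uncalibrated intervals are ``yhat +/- z*sigma_hat`` with
``z`` the standard-normal quantile for the central mass 1-alpha (~1.64 for
90%). The nonconformity score of a calibration pair (x_i, y_i) is the signed
distance from y_i to the nearest interval boundary,

    s_i = max{ y_i - (yhat_i + z*sigma_i), (yhat_i - z*sigma_i) - y_i },

negative when y_i falls inside the interval. The empirical adjustment q-hat
is the k-th smallest score with k = ceil((n+1)(1-alpha)); the calibrated
interval is ``[yhat - z*sigma - qhat, yhat + z*sigma + qhat]``. The
adjustment folds into a calibrated standard deviation

    sigma_cal = sigma_hat + qhat / z,

from which intervals at any confidence level can be rebuilt (the 1-alpha
level is guaranteed; other levels additionally assume Gaussian residuals).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ALPHA",
    "default_z",
    "UQPrediction",
    "CalibrationRecord",
    "ConformalAdjustment",
    "PredictionInterval",
    "nonconformity_score",
    "conformal_quantile",
    "calibrate",
    "calibrate_from_records",
    "predict_interval",
    "calibrated_sigma",
]

DEFAULT_ALPHA = 0.1


def default_z(alpha: float = DEFAULT_ALPHA) -> float:
    """Normal multiplier for central mass 1-alpha (alpha=0.1 -> ~1.6449)."""
    return float(norm.ppf(1.0 - alpha / 2.0))


@dataclass(frozen=True)
class UQPrediction:
    """Point prediction and heuristic standard deviation for one input."""

    y_hat: float
    sigma_hat: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.y_hat) and math.isfinite(self.sigma_hat)):
            raise ValueError("prediction must be finite")
        if self.sigma_hat < 0:
            raise ValueError(f"sigma_hat must be >= 0, got {self.sigma_hat}")


@dataclass(frozen=True)
class CalibrationRecord:
    """One held-out calibration example: input, truth, model prediction."""

    x: np.ndarray
    y: float
    prediction: UQPrediction


@dataclass(frozen=True)
class PredictionInterval:
    lower: float
    upper: float
    level: float

    def contains(self, y: float) -> bool:
        return self.lower <= y <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class ConformalAdjustment:
    """Fitted split-conformal calibration state."""

    alpha: float
    z: float
    scores: np.ndarray
    q_hat: float
    n: int = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.z <= 0:
            raise ValueError("z must be positive")
        self.scores = np.asarray(self.scores, dtype=float)
        self.n = int(self.scores.size)

    def to_json(self, path: str | Path | None = None, model_ref: str | None = None) -> str:
        payload = json.dumps(
            {
                "alpha": self.alpha,
                "z": self.z,
                "q_hat": None if math.isinf(self.q_hat) else self.q_hat,
                "n": self.n,
                "scores": self.scores.tolist(),
                "model_checkpoint": model_ref,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ConformalAdjustment":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        adj = cls(alpha=d["alpha"], z=d["z"], scores=np.asarray(d["scores"]),
                  q_hat=d["q_hat"] if d["q_hat"] is not None else math.inf)
        if adj.n != d["n"]:
            raise ValueError("stored n inconsistent with stored scores")
        return adj


def nonconformity_score(y: float, pred: UQPrediction, z: float) -> float:
    """Signed distance from y to the nearest uncalibrated interval boundary.

    Negative when y lies inside ``[yhat - z*sigma, yhat + z*sigma]``,
    positive outside; smaller magnitude means better calibration.
    """
    if not math.isfinite(y):
        raise ValueError("y must be finite")
    if z <= 0:
        raise ValueError("z must be positive")
    upper = pred.y_hat + z * pred.sigma_hat
    lower = pred.y_hat - z * pred.sigma_hat
    return max(y - upper, lower - y)


def conformal_quantile(scores: Sequence[float] | np.ndarray, alpha: float) -> float:
    """Finite-sample calibration quantile of the nonconformity scores.

    Returns the k-th smallest score with ``k = ceil((n+1)(1-alpha))``; when
    k exceeds n (calibration set too small for the requested level) the
    +inf sentinel is returned, signalling unbounded intervals — the choice
    that preserves the finite-sample coverage guarantee.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = scores.size
    k = math.ceil((n + 1) * (1.0 - alpha))
    if k > n:
        return math.inf
    return float(np.sort(scores, kind="stable")[k - 1])


def calibrate(
    model,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    z: float | None = None,
) -> ConformalAdjustment:
    """Fit the conformal adjustment on a held-out calibration set.

    ``model.predict(X) -> (yhat, sigma_hat)`` arrays. The calibration set
    must be disjoint from the model's training data (caller contract).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_cal.size == 0:
        raise ValueError("empty calibration set")
    z = default_z(alpha) if z is None else float(z)
    y_hat, sigma_hat = model.predict(X_cal)
    upper = y_hat + z * sigma_hat
    lower = y_hat - z * sigma_hat
    scores = np.maximum(y_cal - upper, lower - y_cal)
    q_hat = conformal_quantile(scores, alpha)
    return ConformalAdjustment(alpha=alpha, z=z, scores=scores, q_hat=q_hat)


def calibrate_from_records(
    records: Sequence[CalibrationRecord],
    alpha: float = DEFAULT_ALPHA,
    z: float | None = None,
) -> ConformalAdjustment:
    """Variant of :func:`calibrate` for precomputed prediction records."""
    if len(records) == 0:
        raise ValueError("empty calibration set")
    z = default_z(alpha) if z is None else float(z)
    scores = np.array([nonconformity_score(r.y, r.prediction, z) for r in records])
    return ConformalAdjustment(alpha=alpha, z=z, scores=scores,
                               q_hat=conformal_quantile(scores, alpha))


def predict_interval(pred: UQPrediction, adj: ConformalAdjustment) -> PredictionInterval:
    """Calibrated interval ``[yhat - z*sigma - qhat, yhat + z*sigma + qhat]``.

    A negative q-hat narrows the interval; the +inf sentinel yields an
    unbounded interval.
    """
    half = adj.z * pred.sigma_hat + adj.q_hat
    return PredictionInterval(
        lower=pred.y_hat - half, upper=pred.y_hat + half, level=1.0 - adj.alpha
    )


def calibrated_sigma(pred: UQPrediction, adj: ConformalAdjustment) -> float:
    """Calibrated standard deviation ``sigma_hat + qhat / z``.

    Rebuilding the 1-alpha interval as ``yhat +/- z * sigma_cal`` reproduces
    :func:`predict_interval` exactly; other levels assume Gaussian
    residuals. A negative value (strongly negative q-hat with tiny
    sigma-hat) is clamped to 0 with a logged warning.
    """
    sigma = pred.sigma_hat + adj.q_hat / adj.z
    if sigma < 0:
        logger.warning(
            "calibrated sigma %.4g < 0 (sigma_hat=%.4g, q_hat=%.4g, z=%.4g); clamping to 0",
            sigma, pred.sigma_hat, adj.q_hat, adj.z,
        )
        return 0.0
    return float(sigma)
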