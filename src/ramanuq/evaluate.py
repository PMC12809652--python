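"""Evaluation protocol for calibrated uncertainty estimates.

Covers accuracy metrics (R^2, MAE, MAPE, RMSE), the four uncertainty
metrics (coverage at 90%, sharpness = Median[sigma], consistency =
Var[sigma], informativeness = Corr[|error|, sigma]), coverage curves across
confidence levels with a calibration RMSE summary (levels 5%..95% in 5%
steps plus 99%), the before/after-conformalization ablation, and repeated
cross-validation with median-coverage-error model selection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.stats import norm, pearsonr
from sklearn.model_selection import KFold

from .conformal import (
    DEFAULT_ALPHA,
    ConformalAdjustment,
    PredictionInterval,
    calibrate,
    default_z,
)

__all__ = [
    "DEFAULT_LEVELS",
    "UncertaintyReport",
    "CVPlan",
    "CVResult",
    "empirical_coverage",
    "coverage_curve",
    "uncertainty_metrics",
    "accuracy_metrics",
    "cross_validate",
    "ablate_conformalization",
    "render_coverage_table",
    "plot_calibration_curve",
]

# 5% .. 95% in 5% increments, plus 99%
DEFAULT_LEVELS: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2)) + (0.99,)


def empirical_coverage(
    y_true: np.ndarray, intervals: Sequence[PredictionInterval]
) -> float:
    """Fraction of true values inside their interval (boundaries covered)."""
    y_true = np.asarray(y_true, dtype=float)
    if y_true.size == 0 or len(intervals) == 0:
        raise ValueError("empty inputs")
    if y_true.size != len(intervals):
        raise ValueError("y_true and intervals must have equal length")
    hits = [iv.lower <= y <= iv.upper for y, iv in zip(y_true, intervals)]
    return float(np.mean(hits))


def accuracy_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """R^2 (1 - SSres/SStot), MAE, MAPE (%), RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    if np.any(y_true == 0):
        raise ValueError("MAPE undefined: y_true contains zeros")
    resid = y_true - y_pred
    sstot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sstot if sstot > 0 else float("nan")
    return {
        "r2": r2,
        "mae": float(np.abs(resid).mean()),
        "mape": float((np.abs(resid) / np.abs(y_true)).mean() * 100.0),
        "rmse": float(np.sqrt((resid**2).mean())),
    }


def uncertainty_metrics(
    y_true: np.ndarray, y_hat: np.ndarray, sigma: np.ndarray
) -> tuple[float, float, float | None]:
    """(sharpness, consistency, informativeness).

    sharpness = Median[sigma]; consistency = Var[sigma]; informativeness =
    Pearson Corr[|y - y_hat|, sigma]. With constant sigma the correlation is
    undefined and returned as ``None`` (flagged, not silently zero).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty inputs")
    sharpness = float(np.median(sigma))
    consistency = float(np.var(sigma))
    abs_err = np.abs(y_true - y_hat)
    if np.ptp(sigma) < 1e-15 or np.ptp(abs_err) < 1e-15:
        informativeness = None
    else:
        informativeness = float(pearsonr(abs_err, sigma).statistic)
    return sharpness, consistency, informativeness


@dataclass
class UncertaintyReport:
    """All evaluation outputs for one model on one test set."""

    coverage_by_level: dict[float, float]
    calibration_rmse: float
    sharpness: float
    consistency: float
    informativeness: float | None
    accuracy: dict[str, float] = field(default_factory=dict)
    conformalized: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "coverage_by_level": {f"{k:g}": v for k, v in self.coverage_by_level.items()},
                "calibration_rmse": self.calibration_rmse,
                "sharpness": self.sharpness,
                "consistency": self.consistency,
                "informativeness": self.informativeness,
                "accuracy": self.accuracy,
                "conformalized": self.conformalized,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def coverage_curve(
    y_true: np.ndarray,
    y_hat: np.ndarray,
    sigma_hat: np.ndarray,
    adj: ConformalAdjustment | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> UncertaintyReport:
    """Empirical coverage across confidence levels, Gaussian interval build.

    For each level L the interval is ``y_hat +/- z_L * sigma`` with
    ``z_L = Phi^-1(0.5 + L/2)``. With a conformal adjustment, sigma is the
    calibrated ``sigma_hat + q_hat / z`` (clamped at 0); without one, the raw
    sigma_hat (the before-conformalization mode). The calibration RMSE is the
    root-mean-square gap between empirical and nominal coverage over the
    level ladder.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    for L in levels:
        if not 0.0 < L < 1.0:
            raise ValueError(f"invalid confidence level {L}")
    if adj is not None:
        if math.isinf(adj.q_hat):
            sigma = np.full_like(sigma_hat, np.inf)
        else:
            sigma = np.maximum(sigma_hat + adj.q_hat / adj.z, 0.0)
    else:
        sigma = sigma_hat
    cov: dict[float, float] = {}
    for L in levels:
        z_l = float(norm.ppf(0.5 + L / 2.0))
        half = z_l * sigma
        inside = np.abs(y_true - y_hat) <= half
        cov[float(L)] = float(np.mean(inside))
    rmse = float(np.sqrt(np.mean([(cov[float(L)] - L) ** 2 for L in levels])))
    sharp, consist, informative = uncertainty_metrics(y_true, y_hat, sigma)
    return UncertaintyReport(
        coverage_by_level=cov,
        calibration_rmse=rmse,
        sharpness=sharp,
        consistency=consist,
        informativeness=informative,
        accuracy=accuracy_metrics(y_true, y_hat),
        conformalized=adj is not None,
    )


class CVPlan(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_folds: int = 10
    n_repeats_per_fold: int = 10
    calibration_size: int = 100
    alpha: float = DEFAULT_ALPHA
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CVPlan":
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats_per_fold < 1 or self.calibration_size < 1:
            raise ValueError("n_repeats_per_fold and calibration_size must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        return self


@dataclass
class CVResult:
    fold_reports: list[UncertaintyReport]
    y_hat: np.ndarray  # one aggregated prediction per dataset sample
    sigma_cal: np.ndarray  # calibrated sigma per sample
    y_true: np.ndarray
    selected_coverage_errors: list[float]
    overall: UncertaintyReport | None = None


def _lower_median_index(values: Sequence[float]) -> int:
    order = np.argsort(values, kind="stable")
    return int(order[(len(values) - 1) // 2])


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    model_factory: Callable[[int], object],
    plan: CVPlan | None = None,
) -> CVResult:
    """Repeated split-conformal cross-validation.

    For each of ``n_folds`` folds, ``n_repeats_per_fold`` models are built:
    each draws a fresh random calibration split of ``calibration_size``
    samples from the training folds, trains on the remainder
    (``model_factory(seed)`` returns an unfitted model with ``fit`` and
    ``predict``), conformalizes on the calibration split and is evaluated on
    the held-out fold. Per fold, the model whose |empirical 90% coverage -
    nominal| is the (lower) median of the repeats is selected; the selected
    models' predictions are concatenated so every sample in the dataset
    receives exactly one prediction.
    """
    plan = plan or CVPlan()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    min_fold = n // plan.n_folds
    if plan.calibration_size >= n - min_fold:
        raise ValueError(
            f"calibration_size={plan.calibration_size} infeasible for "
            f"{n} samples in {plan.n_folds} folds"
        )
    rng = np.random.default_rng(plan.seed)
    splitter = KFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
    y_hat = np.full(n, np.nan)
    sigma_cal = np.full(n, np.nan)
    fold_reports: list[UncertaintyReport] = []
    selected_errors: list[float] = []
    level = 1.0 - plan.alpha
    for train_idx, test_idx in splitter.split(X):
        candidates = []
        for _ in range(plan.n_repeats_per_fold):
            cal_pick = rng.choice(train_idx, size=plan.calibration_size, replace=False)
            fit_idx = np.setdiff1d(train_idx, cal_pick)
            model = model_factory(int(rng.integers(2**31 - 1)))
            model.fit(X[fit_idx], y[fit_idx])
            adj = calibrate(model, X[cal_pick], y[cal_pick], alpha=plan.alpha)
            mu, sig = model.predict(X[test_idx])
            sig_c = np.maximum(sig + adj.q_hat / adj.z, 0.0)
            inside = np.abs(y[test_idx] - mu) <= adj.z * sig + adj.q_hat
            cov = float(np.mean(inside))
            candidates.append((abs(cov - level), mu, sig, adj))
        pick = _lower_median_index([c[0] for c in candidates])
        err, mu, sig, adj = candidates[pick]
        selected_errors.append(err)
        sig_c = np.maximum(sig + adj.q_hat / adj.z, 0.0)
        y_hat[test_idx] = mu
        sigma_cal[test_idx] = sig_c
        fold_reports.append(coverage_curve(y[test_idx], mu, sig, adj))
    overall = coverage_curve(y, y_hat, sigma_cal)  # sigma already calibrated
    return CVResult(
        fold_reports=fold_reports,
        y_hat=y_hat,
        sigma_cal=sigma_cal,
        y_true=y.copy(),
        selected_coverage_errors=selected_errors,
        overall=overall,
    )


def ablate_conformalization(
    models: dict[str, object],
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> dict[str, pd.DataFrame]:
    """Before/after/delta coverage tables for fitted models.

    Each model is conformalized on ``(X_cal, y_cal)`` and evaluated on the
    test set with and without the adjustment; ``delta`` is after minus
    before. Display columns follow the canonical level subset plus the
    RMSE summary over the full level ladder.
    """
    if len(models) == 0:
        raise ValueError("need at least one fitted model")
    show = [0.1, 0.2, 0.5, 0.8, 0.9, 0.95, 0.99]
    rows_after, rows_before, rows_delta, reports = {}, {}, {}, {}
    for name, model in models.items():
        adj = calibrate(model, X_cal, y_cal, alpha=alpha)
        mu, sig = model.predict(X_test)
        after = coverage_curve(y_test, mu, sig, adj, levels)
        before = coverage_curve(y_test, mu, sig, None, levels)
        reports[name] = {"after": after, "before": before, "adjustment": adj}
        rows_after[name] = [after.calibration_rmse] + [after.coverage_by_level[L] for L in show]
        rows_before[name] = [before.calibration_rmse] + [
            before.coverage_by_level[L] for L in show
        ]
        rows_delta[name] = [a - b for a, b in zip(rows_after[name], rows_before[name])]
    cols = ["RMSE"] + [f"{int(L * 100)}%" for L in show]
    return {
        "after": pd.DataFrame.from_dict(rows_after, orient="index", columns=cols),
        "before": pd.DataFrame.from_dict(rows_before, orient="index", columns=cols),
        "delta": pd.DataFrame.from_dict(rows_delta, orient="index", columns=cols),
        "reports": reports,
    }


def render_coverage_table(tables: dict[str, pd.DataFrame]) -> str:
    """Human-readable before/after/delta coverage tables."""
    parts = []
    for key, title in (
        ("after", "(a) after conformalization"),
        ("before", "(b) before conformalization"),
        ("delta", "(c) after - before"),
    ):
        if key in tables:
            parts.append(title)
            parts.append(tables[key].round(3).to_string())
            parts.append("")
    return "\n".join(parts)


def plot_calibration_curve(
    reports: dict[str, UncertaintyReport], path: str | Path
) -> Path:
    """Expected-vs-achieved coverage plot with the ideal diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="ideal")
    for name, rep in reports.items():
        levels = sorted(rep.coverage_by_level)
        ax.plot(levels, [rep.coverage_by_level[L] for L in levels], marker="o",
                ms=3, label=name)
    ax.set_xlabel("expected coverage")
    ax.set_ylabel("achieved coverage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
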