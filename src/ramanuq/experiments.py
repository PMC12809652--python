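"""Reusable study drivers: dataset simulation + model-agnostic coverage studies.

The coverage replication study is the package's central validity check: for a
*fixed* base regressor (even a deliberately mis-scaled one), repeated fresh
draws of a calibration set and a test set from the synthetic generator must
produce conformalized 90% intervals whose mean empirical coverage sits at or
above the nominal level, up to the finite-sample upper slack 1/(n_cal + 1)
and Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .conformal import DEFAULT_ALPHA, calibrate
from .preprocess import PreprocessConfig, preprocess_dataset
from .synthetic import SyntheticConfig, generate_dataset

__all__ = [
    "fast_conditions",
    "simulate_preprocessed",
    "LinearSOCModel",
    "MisscaledModel",
    "CoverageStudyResult",
    "coverage_replication_study",
]


def fast_conditions(seed: int = 0, n_samples: int = 100) -> tuple[SyntheticConfig, PreprocessConfig]:
    """Reduced-size study conditions for replication loops.

    Same statistical structure as the defaults (dominant fluorescence,
    albedo confounder, heteroscedastic labels) on a single grid position
    with two replicates and a 2 cm^-1 axis, so that hundreds of fresh
    datasets can be drawn in minutes on one CPU.
    """
    syn = SyntheticConfig(
        n_samples=n_samples,
        grid_shape=(1, 1),
        n_replicates=2,
        axis_start=330.0,
        axis_stop=1420.0,
        axis_step=2.0,
        seed=seed,
    )
    pre = PreprocessConfig(
        grid_start=350.0, grid_stop=1350.0, grid_step=2.0, cmr_levels=4, cmr_iterations=2
    )
    return syn, pre


def simulate_preprocessed(
    syn: SyntheticConfig, pre: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a dataset and run the full preprocessing chain: (X, y)."""
    samples = generate_dataset(syn)
    return preprocess_dataset(samples, pre or PreprocessConfig())


class LinearSOCModel:
    """Ridge point regressor with a constant residual-based sigma.

    A deliberately crude heuristic: sigma-hat is the training residual
    standard deviation times ``sigma_scale`` for every input, so
    ``sigma_scale=0.5`` yields a model whose raw intervals under-cover by
    construction — the case conformal calibration must repair.
    """

    def __init__(self, alpha: float = 1.0, sigma_scale: float = 1.0):
        self.ridge = Ridge(alpha=alpha)
        self.sigma_scale = float(sigma_scale)
        self.sigma_: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSOCModel":
        self.ridge.fit(X, y)
        resid = y - self.ridge.predict(X)
        self.sigma_ = float(resid.std(ddof=1)) * self.sigma_scale
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.sigma_ is None:
            raise RuntimeError("model is not fitted")
        mu = self.ridge.predict(X)
        return mu, np.full_like(mu, self.sigma_)


class MisscaledModel:
    """Wrap any (y_hat, sigma_hat) model and rescale its sigma by a factor."""

    def __init__(self, model, factor: float = 0.5):
        self.model = model
        self.factor = float(factor)

    def fit(self, X, y):
        self.model.fit(X, y)
        return self

    def predict(self, X):
        mu, sig = self.model.predict(X)
        return mu, sig * self.factor


@dataclass
class CoverageStudyResult:
    coverages: np.ndarray  # one empirical 90% coverage per replication
    n_cal: int
    n_test: int
    alpha: float

    @property
    def mean_coverage(self) -> float:
        return float(self.coverages.mean())

    @property
    def se(self) -> float:
        """Monte-Carlo standard error of the replication mean."""
        return float(self.coverages.std(ddof=1) / np.sqrt(self.coverages.size))

    @property
    def guarantee_band(self) -> tuple[float, float]:
        """(lower, upper) band for the mean: 1-alpha - 2SE .. 1-alpha + 1/(n+1) + 2SE."""
        lo = 1.0 - self.alpha - 2.0 * self.se
        hi = 1.0 - self.alpha + 1.0 / (self.n_cal + 1) + 2.0 * self.se
        return lo, hi


def coverage_replication_study(
    model,
    n_replications: int = 200,
    n_cal: int = 100,
    n_test: int = 500,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    conditions: tuple[SyntheticConfig, PreprocessConfig] | None = None,
) -> CoverageStudyResult:
    """Marginal-coverage study for a fixed, already-fitted base model.

    For each replication, ``n_cal`` calibration and ``n_test`` test pairs are
    drawn fresh from the synthetic generator (seeded independently per
    replication), the conformal adjustment is fitted on the calibration
    pairs, and the empirical coverage of the calibrated 1-alpha intervals is
    recorded on the test pairs.
    """
    syn0, pre = conditions if conditions is not None else fast_conditions()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replications) % (2**31 - 1)
    coverages = np.empty(n_replications)
    for r in range(n_replications):
        syn = syn0.model_copy(
            update={"n_samples": n_cal + n_test, "seed": int(child_seeds[r])}
        )
        X, y = simulate_preprocessed(syn, pre)
        X_cal, y_cal = X[:n_cal], y[:n_cal]
        X_te, y_te = X[n_cal:], y[n_cal:]
        adj = calibrate(model, X_cal, y_cal, alpha=alpha)
        mu, sig = model.predict(X_te)
        inside = np.abs(y_te - mu) <= adj.z * sig + adj.q_hat
        coverages[r] = float(np.mean(inside))
    return CoverageStudyResult(coverages=coverages, n_cal=n_cal, n_test=n_test, alpha=alpha)
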