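"""Five interchangeable uncertainty-quantifying regressors on one CNN backbone.

Every model exposes the same contract, ``predict(X) -> (y_hat, sigma_hat)``:

- ``het_gaussian`` — two-head network (mean, log-sigma) trained by Gaussian
  negative log-likelihood; sigma-hat models input-dependent (aleatoric) noise.
- ``quantile`` — three heads at levels {0.05, 0.5, 0.95} trained by pinball
  loss; y-hat is the median head and sigma-hat = (q95 - q05) / (2 * 1.6449),
  the span divided by twice the normal 95th percentile, so a Gaussian
  predictive distribution reproduces the trained quantiles.
- ``mc_dropout`` — point network with dropout kept active at inference;
  mean/sd over ``n_mc_passes`` stochastic passes (epistemic spread).
- ``bayes_backprop`` — mean-field Gaussian weight posteriors trained on the
  variational ELBO (one posterior draw per step); mean/sd over posterior
  weight draws at prediction.
- ``deep_ensemble`` — independently seeded point networks; mean/sd over the
  member predictions.

Sampling-based sigma-hat uses the sample (n-1) standard deviation. All
randomness is owned by explicit seeds: training is reproducible from
``TrainingConfig.seed`` and prediction from the model's ``rng_seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .nn import Adam, Backbone, BackboneConfig, Tensor

__all__ = [
    "METHODS",
    "TrainingConfig",
    "TrainingFailure",
    "UQRegressorBase",
    "HetGaussianRegressor",
    "QuantileRegressor",
    "MCDropoutRegressor",
    "BayesBackpropRegressor",
    "DeepEnsembleRegressor",
    "aggregate_samples",
    "train",
    "make_ensemble",
    "load_model",
    "Z_90",
]

# standard-normal 95th percentile: the multiplier turning a sigma into a
# 90% central interval half-width
Z_90 = 1.6448536269514722

METHODS = ("het_gaussian", "quantile", "mc_dropout", "bayes_backprop", "deep_ensemble")


class TrainingFailure(RuntimeError):
    """Raised when the loss turns non-finite; carries diagnostics."""


class TrainingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    clip_norm: float = 5.0
    seed: int = 0  # fixes initialisation and batch order
    warmup_epochs: int = 20  # mean-only warm-up (het_gaussian)
    validation_fraction: float = 0.0
    early_stopping_patience: int | None = None
    standardize_labels: bool = True

    @model_validator(mode="after")
    def _check(self) -> "TrainingConfig":
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5)")
        return self


@dataclass
class _Standardizer:
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, standardize_labels: bool) -> "_Standardizer":
        x_sd = X.std(axis=0)
        x_sd[x_sd < 1e-12] = 1.0
        if not standardize_labels:
            return cls(X.mean(axis=0), x_sd, 0.0, 1.0)
        y_sd = float(y.std())
        return cls(X.mean(axis=0), x_sd, float(y.mean()), y_sd if y_sd > 1e-12 else 1.0)

    def fx(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_sd

    def fy(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_sd

    def inv_y(self, y: np.ndarray) -> np.ndarray:
        return y * self.y_sd + self.y_mean

    def inv_sigma(self, s: np.ndarray) -> np.ndarray:
        return s * self.y_sd


def aggregate_samples(samples: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample standard deviation over stochastic passes/members.

    ``samples`` has shape (n_passes, n_inputs). With a single pass the
    spread is 0 by convention.
    """
    samples = np.asarray(samples, dtype=float)
    mean = samples.mean(axis=0)
    if samples.shape[0] <= ddof:
        return mean, np.zeros_like(mean)
    return mean, samples.std(axis=0, ddof=ddof)


class UQRegressorBase:
    """Shared training loop and (de)serialisation for the single-network methods."""

    method: str = ""
    n_heads: int = 1
    bayesian: bool = False

    def __init__(self, backbone_config: BackboneConfig | None = None, rng_seed: int = 0):
        self.backbone_config = backbone_config or BackboneConfig()
        if self.backbone_config.output_heads != self.n_heads:
            self.backbone_config = self.backbone_config.model_copy(
                update={"output_heads": self.n_heads}
            )
        self.rng_seed = int(rng_seed)
        self.net: Backbone | None = None
        self.standardizer: _Standardizer | None = None
        self.training_config: TrainingConfig | None = None

    # -- subclass hooks ----------------------------------------------------
    def _loss(self, out: Tensor, y: Tensor, epoch: int, cfg: TrainingConfig) -> Tensor:
        raise NotImplementedError

    def _predict_std(self, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(y_hat, sigma_hat) on the standardized scale."""
        raise NotImplementedError

    # -- API ---------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, config: TrainingConfig | None = None):
        config = config or TrainingConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError(f"shape mismatch: X {X.shape} vs y {y.shape}")
        self.training_config = config
        self.standardizer = _Standardizer.fit(X, y, config.standardize_labels)
        Xs, ys = self.standardizer.fx(X), self.standardizer.fy(y)

        rng = np.random.default_rng(config.seed)
        self.net = Backbone(self.backbone_config, seed=int(rng.integers(2**31 - 1)),
                            bayesian=self.bayesian)
        self._init_extras(Xs, ys)

        n = Xs.shape[0]
        idx = np.arange(n)
        n_val = int(round(config.validation_fraction * n))
        if n_val > 0:
            rng.shuffle(idx)
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
        else:
            val_idx, tr_idx = np.array([], dtype=int), idx

        opt = Adam(
            self.net.parameters(),
            lr=config.learning_rate,
            weight_decay=config.weight_decay,
            clip_norm=config.clip_norm,
        )
        best_val, best_state, patience_left = np.inf, None, config.early_stopping_patience
        self._n_train = tr_idx.size
        for epoch in range(config.epochs):
            order = rng.permutation(tr_idx)
            for start in range(0, order.size, config.batch_size):
                batch = order[start : start + config.batch_size]
                if batch.size < 2:
                    continue  # batchnorm needs >1 sample
                self._pre_step(rng)
                out = self.net.forward(Xs[batch], training=True, dropout_rng=rng)
                loss = self._loss(out, Tensor(ys[batch][:, None]), epoch, config)
                if not np.isfinite(loss.data):
                    raise TrainingFailure(
                        f"{self.method}: non-finite loss at epoch {epoch} "
                        f"(lr={config.learning_rate}, batch={batch.size})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
            if n_val > 0 and patience_left is not None:
                val = self._eval_loss(Xs[val_idx], ys[val_idx], epoch, config)
                if val < best_val - 1e-6:
                    best_val, best_state = val, self.net.state_arrays()
                    best_state = {k: v.copy() for k, v in best_state.items()}
                    patience_left = config.early_stopping_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_state is not None:
            self.net.load_state_arrays(best_state)
        return self

    def _init_extras(self, Xs: np.ndarray, ys: np.ndarray) -> None:
        pass

    def _pre_step(self, rng: np.random.Generator) -> None:
        pass

    def _eval_loss(self, Xv: np.ndarray, yv: np.ndarray, epoch: int, cfg) -> float:
        out = self.net.forward(Xv, training=False)
        return float(self._loss(out, Tensor(yv[:, None]), epoch, cfg).data)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Point prediction and heuristic standard deviation, original units."""
        if self.net is None or self.standardizer is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.backbone_config.input_channels:
            raise ValueError(
                f"input length {X.shape[1]} != backbone input "
                f"{self.backbone_config.input_channels}"
            )
        mu, sigma = self._predict_std(self.standardizer.fx(X))
        return self.standardizer.inv_y(mu), self.standardizer.inv_sigma(sigma)

    # -- checkpoints -------------------------------------------------------
    def _config_payload(self) -> dict:
        return {
            "method": self.method,
            "backbone": self.backbone_config.model_dump(),
            "rng_seed": self.rng_seed,
            "standardizer": {
                "x_mean": self.standardizer.x_mean.tolist(),
                "x_sd": self.standardizer.x_sd.tolist(),
                "y_mean": self.standardizer.y_mean,
                "y_sd": self.standardizer.y_sd,
            },
            "extras": self._extras_payload(),
        }

    def _extras_payload(self) -> dict:
        return {}

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(self._config_payload(), indent=2))
        np.savez(directory / "weights.npz", **self.net.state_arrays())
        return directory

    @classmethod
    def _restore(cls, payload: dict, directory: Path) -> "UQRegressorBase":
        model = cls(BackboneConfig(**payload["backbone"]), rng_seed=payload["rng_seed"])
        model._apply_extras(payload.get("extras", {}))
        st = payload["standardizer"]
        model.standardizer = _Standardizer(
            np.asarray(st["x_mean"]), np.asarray(st["x_sd"]), st["y_mean"], st["y_sd"]
        )
        model.net = Backbone(model.backbone_config, seed=0, bayesian=cls.bayesian)
        with np.load(directory / "weights.npz") as state:
            model.net.load_state_arrays(dict(state))
        return model

    def _apply_extras(self, extras: dict) -> None:
        pass


class HetGaussianRegressor(UQRegressorBase):
    """Heteroscedastic Gaussian: heads (mean, log-sigma), NLL loss.

    The first ``warmup_epochs`` epochs train the mean head by squared error
    while pinning log-sigma near 0 (sigma ~ 1 on the standardized scale),
    which stabilises the likelihood before the variance head is released.
    """

    method = "het_gaussian"
    n_heads = 2

    def _loss(self, out, y, epoch, cfg):
        mu, s = out[:, 0:1], out[:, 1:2]
        if epoch < cfg.warmup_epochs:
            return ((y - mu) ** 2).mean() + 0.01 * (s**2).mean()
        return (s + 0.5 * ((y - mu) ** 2) * (s * (-2.0)).exp()).mean()

    def _predict_std(self, Xs):
        out = self.net.forward(Xs, training=False).data
        return out[:, 0], np.exp(np.clip(out[:, 1], -20, 10))


class QuantileRegressor(UQRegressorBase):
    """Pinball-loss heads at {0.05, 0.5, 0.95}; sigma from the 90% span."""

    method = "quantile"
    n_heads = 3
    levels = (0.05, 0.5, 0.95)

    def _loss(self, out, y, epoch, cfg):
        total = None
        for j, q in enumerate(self.levels):
            diff = y - out[:, j : j + 1]
            pin = (diff * q).maximum(diff * (q - 1.0)).mean()
            total = pin if total is None else total + pin
        return total

    def _predict_std(self, Xs):
        out = np.sort(self.net.forward(Xs, training=False).data, axis=1)  # fix crossings
        q05, q50, q95 = out[:, 0], out[:, 1], out[:, 2]
        return q50, np.maximum(q95 - q05, 0.0) / (2.0 * Z_90)


class MCDropoutRegressor(UQRegressorBase):
    """Squared-error point network; dropout stays on over n_mc_passes at inference."""

    method = "mc_dropout"
    n_heads = 1

    def __init__(self, backbone_config=None, rng_seed: int = 0, n_mc_passes: int = 50):
        super().__init__(backbone_config, rng_seed)
        self.n_mc_passes = int(n_mc_passes)

    def _loss(self, out, y, epoch, cfg):
        return ((y - out) ** 2).mean()

    def _mc_samples(self, Xs: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.rng_seed)  # fresh per call: deterministic
        return np.stack(
            [
                self.net.forward(Xs, training=False, dropout_rng=rng).data[:, 0]
                for _ in range(self.n_mc_passes)
            ]
        )

    def _predict_std(self, Xs):
        return aggregate_samples(self._mc_samples(Xs))

    def _extras_payload(self):
        return {"n_mc_passes": self.n_mc_passes}

    def _apply_extras(self, extras):
        self.n_mc_passes = int(extras.get("n_mc_passes", 50))


class BayesBackpropRegressor(UQRegressorBase):
    """Variational mean-field Gaussian posterior over all weights.

    Minimises the negative ELBO: Gaussian data likelihood with unit variance
    on the standardized labels plus KL(posterior || N(0, prior_sd^2)) scaled
    by 1/n_train, with one posterior draw per training step. Predictive
    sigma-hat is the spread over ``n_mc_passes`` posterior draws — a purely
    epistemic quantity.
    """

    method = "bayes_backprop"
    n_heads = 1
    bayesian = True

    def __init__(
        self,
        backbone_config=None,
        rng_seed: int = 0,
        n_mc_passes: int = 50,
        prior_sd: float = 1.0,
        kl_weight: float = 1.0,
    ):
        super().__init__(backbone_config, rng_seed)
        self.n_mc_passes = int(n_mc_passes)
        self.prior_sd = float(prior_sd)
        self.kl_weight = float(kl_weight)

    def _pre_step(self, rng):
        self.net.sample_weights(rng)

    def _loss(self, out, y, epoch, cfg):
        nll = (0.5 * (y - out) ** 2).mean()
        kl = self.net.kl(self.prior_sd) * (self.kl_weight / max(self._n_train, 1))
        return nll + kl

    def _eval_loss(self, Xv, yv, epoch, cfg):
        self.net.sample_weights(None)  # posterior mean
        out = self.net.forward(Xv, training=False)
        return float((0.5 * (Tensor(yv[:, None]) - out) ** 2).mean().data)

    def _predict_std(self, Xs):
        rng = np.random.default_rng(self.rng_seed)
        draws = []
        for _ in range(self.n_mc_passes):
            self.net.sample_weights(rng)
            draws.append(self.net.forward(Xs, training=False).data[:, 0])
        return aggregate_samples(np.stack(draws))

    def _extras_payload(self):
        return {
            "n_mc_passes": self.n_mc_passes,
            "prior_sd": self.prior_sd,
            "kl_weight": self.kl_weight,
        }

    def _apply_extras(self, extras):
        self.n_mc_passes = int(extras.get("n_mc_passes", 50))
        self.prior_sd = float(extras.get("prior_sd", 1.0))
        self.kl_weight = float(extras.get("kl_weight", 1.0))

    @classmethod
    def _restore(cls, payload, directory):
        model = super()._restore(payload, directory)
        model.net.sample_weights(None)
        return model


class _PointMember(UQRegressorBase):
    method = "point"
    n_heads = 1

    def _loss(self, out, y, epoch, cfg):
        return ((y - out) ** 2).mean()

    def _predict_std(self, Xs):
        out = self.net.forward(Xs, training=False).data[:, 0]
        return out, np.zeros_like(out)


class DeepEnsembleRegressor:
    """Ensemble of independently seeded squared-error networks.

    sigma-hat is the sample standard deviation of the member point
    predictions — the spread of hypotheses reached from different random
    initialisations (epistemic).
    """

    method = "deep_ensemble"

    def __init__(
        self,
        backbone_config: BackboneConfig | None = None,
        rng_seed: int = 0,
        member_seeds: Sequence[int] = (0, 1, 2, 3, 4),
    ):
        if len(member_seeds) == 0:
            raise ValueError("member_seeds must be nonempty")
        if len(set(member_seeds)) < len(member_seeds):
            warnings.warn(
                "duplicate ensemble member seeds reduce hypothesis diversity",
                stacklevel=2,
            )
        self.backbone_config = backbone_config or BackboneConfig()
        self.rng_seed = int(rng_seed)
        self.member_seeds = [int(s) for s in member_seeds]
        self.members: list[_PointMember] = []

    def fit(self, X, y, config: TrainingConfig | None = None):
        config = config or TrainingConfig()
        self.members = []
        for seed in self.member_seeds:
            member = _PointMember(self.backbone_config, rng_seed=self.rng_seed)
            member.fit(X, y, config.model_copy(update={"seed": seed}))
            self.members.append(member)
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if not self.members:
            raise RuntimeError("ensemble is not fitted")
        preds = np.stack([m.predict(X)[0] for m in self.members])
        return aggregate_samples(preds)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps(
                {
                    "method": self.method,
                    "backbone": self.backbone_config.model_dump(),
                    "rng_seed": self.rng_seed,
                    "member_seeds": self.member_seeds,
                },
                indent=2,
            )
        )
        for i, m in enumerate(self.members):
            m.save(directory / f"member_{i}")
        return directory

    @classmethod
    def _restore(cls, payload: dict, directory: Path) -> "DeepEnsembleRegressor":
        model = cls(
            BackboneConfig(**payload["backbone"]),
            rng_seed=payload["rng_seed"],
            member_seeds=payload["member_seeds"],
        )
        for i in range(len(model.member_seeds)):
            sub = directory / f"member_{i}"
            sub_payload = json.loads((sub / "config.json").read_text())
            model.members.append(_PointMember._restore(sub_payload, sub))
        return model


_REGISTRY = {
    "het_gaussian": HetGaussianRegressor,
    "quantile": QuantileRegressor,
    "mc_dropout": MCDropoutRegressor,
    "bayes_backprop": BayesBackpropRegressor,
    "deep_ensemble": DeepEnsembleRegressor,
    "point": _PointMember,
}


def train(
    method: str,
    train_set: tuple[np.ndarray, np.ndarray],
    training_config: TrainingConfig | None = None,
    backbone_config: BackboneConfig | None = None,
    **method_kwargs,
):
    """Train one UQ regressor on ``(spectra matrix, SOC labels)``."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    X, y = train_set
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y >= 100):
        raise ValueError("SOC labels must lie in (0, 100) percent")
    model = _REGISTRY[method](backbone_config, **method_kwargs)
    return model.fit(X, y, training_config)


def make_ensemble(
    member_seeds: Sequence[int],
    train_set: tuple[np.ndarray, np.ndarray],
    training_config: TrainingConfig | None = None,
    backbone_config: BackboneConfig | None = None,
) -> DeepEnsembleRegressor:
    """Train a deep ensemble from explicit member seeds (>= 1, ideally distinct)."""
    model = DeepEnsembleRegressor(backbone_config, member_seeds=member_seeds)
    X, y = train_set
    return model.fit(X, y, training_config)


def load_model(directory: str | Path):
    """Restore any saved UQ model from its checkpoint directory."""
    directory = Path(directory)
    payload = json.loads((directory / "config.json").read_text())
    cls = _REGISTRY[payload["method"]]
    return cls._restore(payload, directory)
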