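"""Layers and the 1-D CNN regression backbone.

The backbone mirrors the standard spectral-CNN design: convolutional blocks
(conv -> ReLU -> batch norm -> max pool) followed by dense blocks
(linear -> ReLU -> dropout) and a final linear head with one output per
required quantity (one for point regression, two for mean + log-sigma,
one per quantile level, ...).

Layers can be built in a *Bayesian* variant where every weight is a
mean-field Gaussian ``w = mu + softplus(rho) * eps``; sampling new weights
and the closed-form KL to a ``N(0, prior_sd^2)`` prior are exposed for
variational training (Bayes by Backprop).
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .autodiff import Tensor, conv1d, maxpool1d

__all__ = ["BackboneConfig", "Dense", "Conv1d", "BatchNorm1d", "Dropout", "Backbone"]


class BackboneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    conv_blocks: list[tuple[int, int, int]] = [(16, 7, 2), (32, 7, 2), (64, 7, 2)]
    dense_blocks: list[tuple[int, float]] = [(128, 0.2), (64, 0.2)]
    input_channels: int = 1650
    output_heads: int = 1

    @model_validator(mode="after")
    def _check(self) -> "BackboneConfig":
        if len(self.conv_blocks) < 1 or len(self.dense_blocks) < 1:
            raise ValueError("need at least one conv block and one dense block")
        for ch, k, p in self.conv_blocks:
            if ch < 1 or k < 1 or p < 1:
                raise ValueError(f"invalid conv block ({ch}, {k}, {p})")
        for w, d in self.dense_blocks:
            if w < 1 or not 0.0 <= d < 1.0:
                raise ValueError(f"invalid dense block ({w}, {d}): dropout must be in [0,1)")
        if self.input_channels < 1 or self.output_heads < 1:
            raise ValueError("input_channels and output_heads must be positive")
        return self


class _Layer:
    bayesian = False

    def parameters(self) -> list[Tensor]:
        return []

    def forward(self, x: Tensor, training: bool) -> Tensor:  # pragma: no cover
        raise NotImplementedError


def _init_gaussian(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class _MaybeBayesParam:
    """A weight tensor, either a plain parameter or a mean-field Gaussian."""

    def __init__(self, rng, shape, fan_in, bayesian: bool, rho_init: float = -5.0):
        self.bayesian = bayesian
        if bayesian:
            self.mu = Tensor(_init_gaussian(rng, shape, fan_in), requires_grad=True)
            self.rho = Tensor(np.full(shape, rho_init), requires_grad=True)
            self._eps: np.ndarray | None = None
        else:
            self.value = Tensor(_init_gaussian(rng, shape, fan_in), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.mu, self.rho] if self.bayesian else [self.value]

    def sample(self, rng: np.random.Generator | None) -> None:
        if self.bayesian:
            if rng is None:  # use the posterior mean
                self._eps = np.zeros(self.mu.data.shape)
            else:
                self._eps = rng.normal(size=self.mu.data.shape)

    def tensor(self) -> Tensor:
        if not self.bayesian:
            return self.value
        if self._eps is None:
            raise RuntimeError("call sample() before forward on a Bayesian layer")
        return self.mu + self.rho.softplus() * self._eps

    def kl(self, prior_sd: float) -> Tensor:
        """KL( N(mu, sigma^2) || N(0, prior_sd^2) ), summed over weights."""
        sigma = self.rho.softplus()
        return (
            Tensor(np.log(prior_sd)) - sigma.log()
            + (sigma**2 + self.mu**2) * (0.5 / prior_sd**2)
            - 0.5
        ).sum()


class Dense(_Layer):
    def __init__(self, rng, n_in: int, n_out: int, bayesian: bool = False):
        self.w = _MaybeBayesParam(rng, (n_in, n_out), n_in, bayesian)
        self.b = _MaybeBayesParam(rng, (n_out,), max(n_in, 1), bayesian)
        if not bayesian:
            self.b.value.data[:] = 0.0
        self.bayesian = bayesian

    def parameters(self):
        return self.w.parameters() + self.b.parameters()

    def forward(self, x: Tensor, training: bool) -> Tensor:
        return x @ self.w.tensor() + self.b.tensor()


class Conv1d(_Layer):
    def __init__(self, rng, c_in: int, c_out: int, kernel: int, bayesian: bool = False):
        fan_in = c_in * kernel
        self.w = _MaybeBayesParam(rng, (c_out, c_in, kernel), fan_in, bayesian)
        self.b = _MaybeBayesParam(rng, (c_out,), fan_in, bayesian)
        if not bayesian:
            self.b.value.data[:] = 0.0
        self.bayesian = bayesian

    def parameters(self):
        return self.w.parameters() + self.b.parameters()

    def forward(self, x: Tensor, training: bool) -> Tensor:
        return conv1d(x, self.w.tensor(), self.b.tensor())


class BatchNorm1d(_Layer):
    """Batch normalisation over (batch, length) per channel; running stats at eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean[None, :, None]
            var = self.running_var[None, :, None]
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class Dropout(_Layer):
    """Inverted dropout; active in training and (for MC dropout) at inference
    when an rng is supplied to the backbone's forward."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: Tensor, training: bool, rng: np.random.Generator | None = None) -> Tensor:
        if self.rate == 0.0 or (not training and rng is None):
            return x
        gen = rng
        if gen is None:
            raise RuntimeError("training-mode dropout requires an rng")
        mask = (gen.random(x.data.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask


class Backbone:
    """1-D CNN: conv blocks -> flatten -> dense blocks -> linear head."""

    def __init__(self, config: BackboneConfig, seed: int, bayesian: bool = False):
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers: list[tuple[str, _Layer]] = []
        c_in, length = 1, config.input_channels
        for ch, kernel, pool in config.conv_blocks:
            if kernel > length:
                raise ValueError(
                    f"conv kernel {kernel} exceeds remaining length {length}; "
                    "shrink the backbone for short inputs"
                )
            self.layers.append(("conv", Conv1d(rng, c_in, ch, kernel, bayesian)))
            self.layers.append(("relu", _ReLU()))
            self.layers.append(("bn", BatchNorm1d(ch)))
            length = (length - kernel + 1) // pool
            if length < 1:
                raise ValueError("pooling collapsed the sequence; reduce pools/kernels")
            self.layers.append(("pool", _Pool(pool)))
            c_in = ch
        self.flat_dim = c_in * length
        n_in = self.flat_dim
        for width, rate in config.dense_blocks:
            self.layers.append(("dense", Dense(rng, n_in, width, bayesian)))
            self.layers.append(("relu", _ReLU()))
            self.layers.append(("dropout", Dropout(rate)))
            n_in = width
        self.layers.append(("head", Dense(rng, n_in, config.output_heads, bayesian)))

    def parameters(self) -> list[Tensor]:
        return [p for _, layer in self.layers for p in layer.parameters()]

    def bayes_params(self) -> list[_MaybeBayesParam]:
        out = []
        for _, layer in self.layers:
            for attr in ("w", "b"):
                p = getattr(layer, attr, None)
                if isinstance(p, _MaybeBayesParam) and p.bayesian:
                    out.append(p)
        return out

    def sample_weights(self, rng: np.random.Generator | None) -> None:
        for p in self.bayes_params():
            p.sample(rng)

    def kl(self, prior_sd: float) -> Tensor:
        total: Tensor | None = None
        for p in self.bayes_params():
            term = p.kl(prior_sd)
            total = term if total is None else total + term
        if total is None:
            raise RuntimeError("kl() called on a non-Bayesian backbone")
        return total

    def forward(
        self,
        x: np.ndarray | Tensor,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(x)
        n = t.data.shape[0]
        t = t.reshape(n, 1, t.data.shape[1])
        flattened = False
        for kind, layer in self.layers:
            if kind in ("dense", "head") and not flattened:
                t = t.reshape(n, self.flat_dim)
                flattened = True
            if kind == "dropout":
                t = layer.forward(t, training, dropout_rng)
            else:
                t = layer.forward(t, training)
        return t

    # -- (de)serialisation -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, (kind, layer) in enumerate(self.layers):
            for j, p in enumerate(layer.parameters()):
                state[f"{i}_{kind}_{j}"] = p.data
            if isinstance(layer, BatchNorm1d):
                state[f"{i}_bn_rmean"] = layer.running_mean
                state[f"{i}_bn_rvar"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, (kind, layer) in enumerate(self.layers):
            for j, p in enumerate(layer.parameters()):
                p.data = np.asarray(state[f"{i}_{kind}_{j}"], dtype=float)
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = np.asarray(state[f"{i}_bn_rmean"], dtype=float)
                layer.running_var = np.asarray(state[f"{i}_bn_rvar"], dtype=float)


class _ReLU(_Layer):
    def forward(self, x: Tensor, training: bool) -> Tensor:
        return x.relu()


class _Pool(_Layer):
    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x: Tensor, training: bool) -> Tensor:
        return x if self.pool == 1 else maxpool1d(x, self.pool)
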