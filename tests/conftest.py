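import numpy as np
import pytest

from ramanuq import (
    BackboneConfig,
    SyntheticConfig,
    TrainingConfig,
    generate_dataset,
    make_ensemble,
    train,
)
from ramanuq.experiments import fast_conditions, simulate_preprocessed


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Small, fast campaign: 6 samples, 2x2 grid, 2 replicates, short axis."""
    return SyntheticConfig(
        n_samples=6,
        grid_shape=(2, 2),
        n_replicates=2,
        axis_start=330.0,
        axis_stop=1420.0,
        axis_step=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def benchmark():
    """Shared desk-scale benchmark: all five UQ methods trained once.

    1300 samples at the reduced study conditions; 1000 train / 100
    calibration / 200 test. Used by the cross-method accuracy comparison and
    the conformalization ablation.
    """
    syn, pre = fast_conditions(seed=42, n_samples=1300)
    X, y = simulate_preprocessed(syn, pre)
    tr, cal, te = slice(0, 1000), slice(1000, 1100), slice(1100, 1300)
    bb = BackboneConfig(
        conv_blocks=[(8, 7, 4), (16, 7, 4)], dense_blocks=[(32, 0.2)],
        input_channels=X.shape[1],
    )
    tc = TrainingConfig(
        epochs=120, warmup_epochs=15, batch_size=32, learning_rate=1e-3,
        validation_fraction=0.15, early_stopping_patience=20, weight_decay=3e-4,
        seed=0,
    )
    tc_bayes = tc.model_copy(update={"weight_decay": 0.0})
    train_set = (X[tr], y[tr])
    models = {
        "het_gaussian": train("het_gaussian", train_set, tc, bb),
        "quantile": train("quantile", train_set, tc, bb),
        "mc_dropout": train("mc_dropout", train_set, tc, bb, n_mc_passes=30),
        "bayes_backprop": train(
            "bayes_backprop", train_set, tc_bayes, bb, n_mc_passes=30
        ),
        "deep_ensemble": make_ensemble([0, 1, 2], train_set, tc, bb),
    }
    return {"X": X, "y": y, "train": tr, "cal": cal, "test": te, "models": models}
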