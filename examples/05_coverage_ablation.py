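"""Before/after conformalization ablation on aleatoric-dominated data.

A deterministic head (heteroscedastic Gaussian) is near-calibrated without
conformalization; a small deep ensemble — whose spread is purely epistemic —
under-covers badly until the conformal adjustment widens it.
"""

from ramanuq import BackboneConfig, TrainingConfig, make_ensemble, train
from ramanuq.evaluate import ablate_conformalization, render_coverage_table
from ramanuq.experiments import fast_conditions, simulate_preprocessed

syn, pre = fast_conditions(seed=8, n_samples=900)
X, y = simulate_preprocessed(syn, pre)
tr, cal, te = slice(0, 650), slice(650, 750), slice(750, 900)

backbone = BackboneConfig(conv_blocks=[(8, 7, 4), (16, 7, 4)],
                          dense_blocks=[(32, 0.2)], input_channels=X.shape[1])
training = TrainingConfig(epochs=100, warmup_epochs=15, validation_fraction=0.15,
                          early_stopping_patience=20, weight_decay=3e-4, seed=0)

models = {
    "het_gaussian": train("het_gaussian", (X[tr], y[tr]), training, backbone),
    "deep_ensemble": make_ensemble([0, 1, 2], (X[tr], y[tr]), training, backbone),
}
tables = ablate_conformalization(models, X[cal], y[cal], X[te], y[te], alpha=0.1)
print(render_coverage_table(tables))
print("reading the tables: the ensemble's before-CP row under-covers at every")
print("level (epistemic-only spread); after conformalization both methods sit")
print("near the diagonal, reproducing the aleatoric-dominated regime")
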