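"""Train the heteroscedastic Gaussian CNN on synthetic spectra and evaluate it.

The two-head network predicts SOC and an input-dependent standard deviation;
after conformalization the evaluation reports coverage, sharpness
(Median[sigma]), consistency (Var[sigma]) and informativeness
(Corr[|error|, sigma]).
"""

from ramanuq import BackboneConfig, TrainingConfig, calibrate, coverage_curve, train
from ramanuq.experiments import fast_conditions, simulate_preprocessed

syn, pre = fast_conditions(seed=5, n_samples=700)
X, y = simulate_preprocessed(syn, pre)
tr, cal, te = slice(0, 500), slice(500, 600), slice(600, 700)

backbone = BackboneConfig(conv_blocks=[(8, 7, 4), (16, 7, 4)],
                          dense_blocks=[(32, 0.2)], input_channels=X.shape[1])
training = TrainingConfig(epochs=100, warmup_epochs=15, validation_fraction=0.15,
                          early_stopping_patience=20, weight_decay=3e-4, seed=0)
model = train("het_gaussian", (X[tr], y[tr]), training, backbone)

adj = calibrate(model, X[cal], y[cal], alpha=0.1)
mu, sigma = model.predict(X[te])
report = coverage_curve(y[te], mu, sigma, adj)

print(f"R^2 = {report.accuracy['r2']:.3f}, MAE = {report.accuracy['mae']:.3f} % SOC")
print(f"coverage(90%) = {report.coverage_by_level[0.9]:.3f}, "
      f"calibration RMSE = {report.calibration_rmse:.3f}")
print(f"sharpness Median[sigma] = {report.sharpness:.3f}, "
      f"consistency Var[sigma] = {report.consistency:.4f}")
print(f"informativeness Corr[|error|, sigma] = {report.informativeness:.3f}")
print("sigma here is the conformally calibrated standard deviation")
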