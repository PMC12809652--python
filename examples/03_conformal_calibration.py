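"""Split-conformal calibration of a deliberately mis-scaled regressor.

A ridge baseline whose heuristic sigma is halved under-covers badly; a
100-sample calibration set and the conformal quantile repair its 90%
intervals on fresh test data — the guarantee is model-agnostic.
"""

import numpy as np

from ramanuq import calibrate, calibrated_sigma, default_z, predict_interval
from ramanuq.conformal import UQPrediction
from ramanuq.experiments import LinearSOCModel, fast_conditions, simulate_preprocessed

syn, pre = fast_conditions(seed=1, n_samples=900)
X, y = simulate_preprocessed(syn, pre)
X_tr, y_tr = X[:300], y[:300]
X_cal, y_cal = X[300:400], y[300:400]
X_te, y_te = X[400:], y[400:]

model = LinearSOCModel(sigma_scale=0.5).fit(X_tr, y_tr)  # sigma deliberately halved
z = default_z(0.1)

mu, sig = model.predict(X_te)
before = np.mean(np.abs(y_te - mu) <= z * sig)

adj = calibrate(model, X_cal, y_cal, alpha=0.1)
after = np.mean(np.abs(y_te - mu) <= z * sig + adj.q_hat)

print(f"nonconformity quantile q_hat = {adj.q_hat:.3f} (n = {adj.n}, alpha = 0.1)")
print(f"90% coverage before conformalization: {before:.3f}  (should under-cover)")
print(f"90% coverage after  conformalization: {after:.3f}  (guaranteed >= 0.9 on average)")

pred = UQPrediction(float(mu[0]), float(sig[0]))
iv = predict_interval(pred, adj)
sigma_cal = calibrated_sigma(pred, adj)
print(f"first test sample: y = {y_te[0]:.2f}, interval [{iv.lower:.2f}, {iv.upper:.2f}], "
      f"calibrated sigma = {sigma_cal:.3f}")
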