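# Methods

`ramanuq` implements a calibrated uncertainty-quantification pipeline for
regression on shifted-excitation Raman difference spectroscopy (SERDS)
measurements, with soil organic carbon (SOC, % by mass) as the target. This
note documents the models, the synthetic data they are exercised on, the
numerical choices, and the limits of what the test suite demonstrates.

## Split-conformal calibration

Any base model exposing `predict(x) -> (ŷ, σ̂)` is treated as a black box.
Uncalibrated 90% intervals are `ŷ ± z σ̂` with `z = Φ⁻¹(0.95) ≈ 1.6449`
(displayed as 1.64). On a held-out calibration set of n pairs the
nonconformity score

    s_i = max{ y_i − (ŷ_i + z σ̂_i), (ŷ_i − z σ̂_i) − y_i }

is the signed distance from the truth to the nearest interval boundary
(negative inside). The adjustment `q̂` is the k-th smallest score with
`k = ⌈(n+1)(1−α)⌉` (α = 0.1 by default); calibrated intervals are
`[ŷ − zσ̂ − q̂, ŷ + zσ̂ + q̂]`. For exchangeable data this guarantees
marginal coverage ≥ 1−α for any base model, however miscalibrated; the
upper side is ≤ 1−α + 1/(n+1) for continuous scores.

The adjustment folds into a calibrated standard deviation
`σ = σ̂ + q̂/z`, chosen over the alternative reading `σ̂ + q̂·z` because it
makes the rebuilt 90% interval `ŷ ± zσ` algebraically identical to the
conformal interval. Intervals at other levels L use `ŷ ± z_L σ`; these are
exact only under Gaussian residuals — an assumption, not a guarantee, and
documented as such wherever coverage curves are reported.

Numerical corner cases, all tested:

- `k > n` (calibration set too small for the level): `q̂ = +∞`, intervals
  unbounded. This preserves the finite-sample guarantee rather than
  silently falling back to the maximum score. The default operating point
  (n = 100, α = 0.1, k = 91) never hits it.
- Ties in scores: the k-th order statistic under a stable sort, which makes
  the implementation bit-identical to a sort-and-index oracle.
- `σ̂ + q̂/z < 0` (strongly negative q̂, tiny σ̂): clamped to 0 with a
  logged warning; the raw value remains visible in the log record.

## Uncertainty heads

A shared 1-D CNN backbone (conv → ReLU → batch norm → max pool blocks, then
dense → ReLU → dropout blocks and a linear head) feeds five interchangeable
uncertainty mechanisms:

| method | σ̂ source | loss |
| --- | --- | --- |
| `het_gaussian` | `exp` of a second head | Gaussian NLL |
| `quantile` | (q̂₀.₉₅ − q̂₀.₀₅) / (2·1.6449) | pinball at {0.05, 0.5, 0.95} |
| `mc_dropout` | sd over stochastic passes | squared error |
| `bayes_backprop` | sd over posterior weight draws | ELBO (unit-variance likelihood) |
| `deep_ensemble` | sd over member predictions | squared error per member |

Choices that matter:

- The networks are trained with a compact reverse-mode autodiff engine
  written on numpy (`ramanuq.nn`), sized for CPU-scale experiments; this
  keeps initialisation, batch order, dropout masks and posterior draws under
  a single explicit seed, so training and prediction are bit-reproducible.
- Sample spreads use the (n−1) standard deviation; a single pass or
  identical members give σ̂ = 0.
- Quantile heads can cross on a finite sample; predictions sort the three
  head outputs, so the span (and σ̂) is never negative. The divisor
  2·1.6449 makes a Gaussian predictive distribution reproduce the trained
  5%/95% quantiles, consistent with the z used for intervals.
- `het_gaussian` trains the mean head alone for `warmup_epochs` (log-σ
  pinned near 0 on the standardized scale) before releasing the NLL —
  without this the variance head can absorb early mean error.
- `bayes_backprop` uses a mean-field Gaussian posterior over all weights,
  a N(0, prior_sd²) prior with closed-form KL scaled by 1/n_train, and one
  posterior draw per training step. The data likelihood has unit variance
  on standardized labels, so its predictive spread is purely epistemic —
  deliberately, as this is the regime the ablation probes.
- Inputs are standardized per channel and labels centred/scaled on the
  training split only; σ̂ is rescaled back through the label scale.
  Leakage-free by construction.

Accuracy across the five methods is kept comparable (pairwise R² gap below
0.1 on the shared benchmark) by using one backbone and one training recipe;
no per-method tuning is performed.

## Synthetic SERDS generator

No public SOC/SERDS dataset exists, so the generator is the package's
test-bed. It emulates the *statistical structure* the pipeline relies on,
not soil physics:

- Per sample: a spatial grid of positions (default 3×3; a 10×10 / 15
  replicate full-scale preset exists), two lasers separated by
  `laser_shift` (10 cm⁻¹) and `n_replicates` (3) replicates per laser,
  200 ms integration time.
- Raman component: six fixed Gaussian bands at 465–1660 cm⁻¹ whose
  amplitudes follow `A_k · soc / (1 + soc/8)` — monotone but saturating, so
  intensity is deliberately not proportional to the label. Laser 2's bands
  are translated by the laser gap; fluorescence is identical across lasers
  up to a 1% smooth tilt. This is exactly the asymmetry SERDS differencing
  and common-mode rejection exploit.
- Fluorescence: a broad hump plus linear ramp, 50× the Raman scale by
  default and mildly increasing with SOC.
- Confounding: a per-sample log-normal albedo factor (sd 0.2 on the log
  scale) multiplies the whole spectrum, so samples with different SOC can
  produce near-identical spectra — the source of irreducible (aleatoric)
  ambiguity.
- Label noise: the spectrum is generated from an effective SOC perturbed by
  N(0, (c₀ + c₁·soc)²) around the reported label (defaults c₀ = 0.1,
  c₁ = 0.05 % SOC), making the label-conditional noise heteroscedastic.
- SOC labels are uniform on [0.28, 6.95] %, the observed field range.

What the generator does **not** reproduce: real Raman cross-sections and
mineral interference, instrument response, cosmic rays, detector
nonlinearity, or the empirical noise spectrum of any spectrometer — none of
these are published for the motivating application. Passing tests therefore
demonstrate the *calibration machinery* (which is distribution-free) and
the *qualitative* aleatoric-vs-epistemic structure, not performance on real
soils.

## Preprocessing chain

Stage order is fixed: MSC across each replicate set (reference = set mean),
replicate averaging and division by integration time, common-mode
rejection per grid position, SERDS difference (laser 2 − laser 1), grid
averaging, Savitzky–Golay smoothing (window 11, order 2), linear resampling
onto the half-open grid [350, 2000) cm⁻¹ at 1 cm⁻¹ — exactly 1650
channels. The half-open convention is deliberate: an inclusive grid would
have 1651 points, and the model-input width is fixed at 1650.

- MSC fits `x ≈ a + b·ref` by least squares and returns `(x − a)/b`; a
  slope below 10⁻⁸ of the reference scale raises a degenerate-spectrum
  error naming the offender. MSC removes *relative* per-spectrum affine
  distortions; a factor common to every replicate propagates linearly
  through the (fully linear) chain — the pipeline is scale-equivariant,
  not scale-invariant, and the tests pin down exactly that.
- Common-mode rejection estimates each channel's smooth background as a
  multi-level wavelet approximation (sym8, 6 levels at full resolution,
  detail coefficients zeroed), refined by 5 clip-to-baseline iterations to
  keep narrow peaks out of the estimate (≤ 10% peak-height loss, tested);
  the channel-2 background is regressed on channel-1 (scale + offset) and
  the fitted shared component subtracted from both. The published
  description of this step is qualitative, so this is a
  faithful-in-spirit implementation with the wavelet, depth and iteration
  count configurable; no bit-equivalence with any in-house variant is
  claimed.
- Savitzky–Golay uses scipy's `mode="interp"` edge policy (polynomial fit
  over the terminal window), so any polynomial of degree ≤ 2 is reproduced
  exactly at every point, edges included.

## Evaluation protocol

- Coverage counts boundary values as covered (the direction that favours
  the guarantee).
- Coverage curves evaluate levels 5%–95% in 5% steps plus 99%; the
  calibration RMSE is the root-mean-square gap to the nominal level over
  that ladder. Before-conformalization curves use raw σ̂, after-curves the
  calibrated σ, matching the ablation's framing. Table-style reports list
  σ statistics (sharpness/consistency/informativeness) on the calibrated
  σ, since they describe the intervals actually issued.
- Informativeness (Pearson correlation of |error| with σ̂) is reported as
  undefined — never silently 0 — when σ̂ is constant.
- Cross-validation: 10 folds by default; per fold, 10 models each with a
  fresh random 100-sample calibration split drawn from the training folds;
  the model whose |90% coverage − 0.90| on the held-out fold is the (lower)
  median of the repeats is selected, and selected-model predictions are
  concatenated so each sample receives exactly one prediction. Folds split
  at sample level by default; grouping correlated samples (e.g. by field of
  origin) is a caller-side choice via the model-factory interface.

## Study sizes

The default test-bed sizes are chosen for single-CPU reproducibility and
are documented as the package's own operating points: the coverage
replication study uses 200 replications of 100 calibration + 500 test
samples drawn from a reduced single-grid-position configuration on a
2 cm⁻¹ axis (500 channels); the cross-method benchmark uses 1300 samples
(1000 train / 100 calibration / 200 test) at the same reduced conditions;
the heteroscedastic-recovery simulation uses n = 2000 with 4 input features
so that `y = x₁ + ε`, `sd(ε|x) = 0.1 + 0.5|x₁|`. The full-scale 10×10×15
configuration and the 1650-channel grid are presets and are exercised by
the channel-count and pipeline tests.

## Known limitations

- The guarantee is marginal: any single calibration draw can over- or
  under-cover (n = 100 gives a ±3% one-sd band at the 90% level); only the
  mean over calibration draws is pinned. Tests therefore average over
  replications.
- Non-90% levels inherit the Gaussian-residual assumption; heavy-tailed
  residuals would show up in the calibration RMSE, not be corrected.
- The NN engine is CPU-oriented and deliberately small; it is not intended
  for large-scale training, and no exhaustive hyperparameter search is
  performed anywhere.
- Conformal variants with per-side adjustments (full CQR), Mondrian/
  conditional conformal and jackknife+ are out of scope.
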