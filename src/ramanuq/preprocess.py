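"""Signal chain from raw replicate measurements to a single model input.

Stages, in fixed order:

1. multiplicative scattering correction (MSC) across each replicate set,
2. replicate averaging + integration-time normalisation,
3. common-mode rejection of the background shared by the two laser channels
   (wavelet-approximation baseline + scale/offset regression),
4. SERDS differencing (laser 2 minus laser 1) to cancel fluorescence,
5. averaging of the difference spectra over grid positions,
6. Savitzky-Golay smoothing (window 11, order 2 by default),
7. linear resampling onto a uniform half-open grid [350, 2000) cm^-1 at
   1 cm^-1 — exactly 1650 channels at defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pywt
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.signal import savgol_filter

from .spectrum import Spectrum
from .synthetic import RawSample

__all__ = [
    "PreprocessConfig",
    "PreprocessError",
    "DegenerateSpectrumError",
    "msc_correct",
    "average_replicates",
    "common_mode_rejection",
    "serds_difference",
    "average_grid",
    "savgol_smooth",
    "resample_uniform",
    "preprocess_sample",
    "preprocess_dataset",
    "write_spectrum",
    "write_dataset_matrix",
    "read_dataset_matrix",
]


class PreprocessError(RuntimeError):
    """Raised by a preprocessing stage; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class DegenerateSpectrumError(PreprocessError):
    """MSC slope |b| below tolerance — the spectrum carries no reference signal."""


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sg_window: int = 11
    sg_polyorder: int = 2
    grid_start: float = 350.0  # cm^-1
    grid_stop: float = 2000.0
    grid_step: float = 1.0
    cmr_levels: int = 6  # wavelet decomposition depth for the baseline
    cmr_wavelet: str = "sym8"
    cmr_iterations: int = 5  # baseline refinement passes (clip-to-signal)

    @model_validator(mode="after")
    def _check(self) -> "PreprocessConfig":
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")
        if self.grid_stop <= self.grid_start:
            raise ValueError("grid_stop must exceed grid_start")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.cmr_levels < 1:
            raise ValueError("cmr_levels must be >= 1")
        return self

    def target_grid(self) -> np.ndarray:
        """Half-open uniform grid [start, stop) — 1650 channels at defaults."""
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step))
        return self.grid_start + self.grid_step * np.arange(n)


def _require_common_axis(stage: str, *spectra: Spectrum) -> None:
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_axis(s):
            raise PreprocessError(stage, "spectra are not on a common wavenumber axis")


def msc_correct(
    spectra: Sequence[Spectrum],
    reference: Spectrum | str = "mean",
    slope_tol: float = 1e-8,
) -> list[Spectrum]:
    """Multiplicative scattering correction against a reference spectrum.

    Each spectrum ``x`` is regressed on the reference, ``x ~ a + b*ref``
    (ordinary least squares over channels), and corrected to ``(x - a)/b``,
    removing per-spectrum additive offsets and multiplicative scaling
    relative to the reference. ``reference="mean"`` uses the mean spectrum of
    the input set (requires >= 2 spectra); the reference maps to itself.

    Raises :class:`DegenerateSpectrumError` (naming the offender) when the
    fitted slope magnitude falls below ``slope_tol`` times the reference
    scale — e.g. a constant spectrum against a non-constant reference.
    """
    if len(spectra) == 0:
        raise PreprocessError("msc", "empty spectrum list")
    if isinstance(reference, str):
        if reference != "mean":
            raise PreprocessError("msc", f"unknown reference {reference!r}")
        if len(spectra) < 2:
            raise PreprocessError("msc", "reference='mean' needs at least 2 spectra")
        _require_common_axis("msc", *spectra)
        ref_vec = np.mean([s.intensity for s in spectra], axis=0)
        ref_axis = spectra[0].axis
    else:
        _require_common_axis("msc", reference, *spectra)
        ref_vec = reference.intensity
        ref_axis = reference.axis

    ref_centered = ref_vec - ref_vec.mean()
    denom = float(ref_centered @ ref_centered)
    if denom <= 0:
        raise PreprocessError("msc", "reference spectrum is constant; MSC undefined")
    ref_scale = float(np.sqrt(denom / ref_vec.size))

    out = []
    for idx, s in enumerate(spectra):
        x = s.intensity
        b = float(ref_centered @ (x - x.mean())) / denom
        a = float(x.mean() - b * ref_vec.mean())
        if abs(b) < slope_tol * max(ref_scale, 1.0):
            name = s.meta.get("sample_id", f"spectrum #{idx}")
            raise DegenerateSpectrumError(
                "msc", f"degenerate spectrum {name}: fitted slope b={b:.3g} ~ 0"
            )
        out.append(Spectrum(ref_axis.copy(), (x - a) / b, dict(s.meta, stage="msc")))
    return out


def average_replicates(
    sample: RawSample, apply_msc: bool = True
) -> dict[tuple[int, int], Spectrum]:
    """Collapse each (grid position, laser) replicate set to one spectrum.

    MSC is applied across the replicate set (reference = set mean) before the
    arithmetic mean; the mean is then normalised by the integration time.
    Keys are ``(grid_position, laser)`` with laser in {1, 2}.
    """
    n_grid, _, n_rep, _ = sample.measurements.shape
    if n_rep == 0:
        raise PreprocessError("average_replicates", "empty replicate set")
    out: dict[tuple[int, int], Spectrum] = {}
    for g in range(n_grid):
        for laser in (1, 2):
            reps = [
                Spectrum(
                    sample.axis,
                    sample.measurements[g, laser - 1, r],
                    {"sample_id": sample.sample_id, "grid": g, "laser": laser, "rep": r},
                )
                for r in range(n_rep)
            ]
            if apply_msc and n_rep >= 2:
                reps = msc_correct(reps, reference="mean")
            mean = np.mean([s.intensity for s in reps], axis=0) / sample.integration_time
            out[(g, laser)] = Spectrum(
                sample.axis,
                mean,
                {"sample_id": sample.sample_id, "grid": g, "laser": laser,
                 "stage": "replicate_mean"},
            )
    return out


def _wavelet_baseline(
    y: np.ndarray, wavelet: str, levels: int, iterations: int
) -> np.ndarray:
    """Smooth baseline via multi-level wavelet approximation.

    Detail coefficients up to ``levels`` are zeroed; the approximation is
    refined ``iterations`` times by clipping the working signal to the
    current baseline, which suppresses leakage of narrow peaks into the
    estimate.
    """
    max_level = pywt.dwt_max_level(y.size, pywt.Wavelet(wavelet).dec_len)
    if levels > max_level:
        raise PreprocessError(
            "common_mode_rejection",
            f"cmr_levels={levels} too deep for vector length {y.size} "
            f"(max {max_level} with {wavelet})",
        )
    work = y.astype(float)
    baseline = work
    for _ in range(max(1, iterations)):
        coeffs = pywt.wavedec(work, wavelet, level=levels, mode="smooth")
        coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
        baseline = pywt.waverec(coeffs, wavelet, mode="smooth")[: y.size]
        work = np.minimum(work, baseline)
    return baseline


def common_mode_rejection(
    s1: Spectrum, s2: Spectrum, config: PreprocessConfig | None = None
) -> tuple[Spectrum, Spectrum]:
    """Remove the smooth background component shared by the two laser channels.

    Each channel's smooth background is estimated by a multi-level wavelet
    approximation; the channel-2 background is regressed on the channel-1
    background (scale + offset) and the fitted shared component is
    subtracted from each channel. Narrow Raman-scale features live in the
    discarded detail scales and are preserved.
    """
    config = config or PreprocessConfig()
    _require_common_axis("common_mode_rejection", s1, s2)
    b1 = _wavelet_baseline(s1.intensity, config.cmr_wavelet, config.cmr_levels,
                           config.cmr_iterations)
    b2 = _wavelet_baseline(s2.intensity, config.cmr_wavelet, config.cmr_levels,
                           config.cmr_iterations)
    # regression alignment: b2 ~ alpha + beta * b1
    A = np.column_stack([np.ones_like(b1), b1])
    (alpha, beta), *_ = np.linalg.lstsq(A, b2, rcond=None)
    out1 = s1.with_intensity(s1.intensity - b1, stage="cmr")
    out2 = s2.with_intensity(s2.intensity - (alpha + beta * b1), stage="cmr")
    return out1, out2


def serds_difference(s1: Spectrum, s2: Spectrum) -> Spectrum:
    """SERDS difference: laser-2 intensity minus laser-1 intensity.

    Raman bands shift with the excitation while fluorescence does not, so the
    shared fluorescence cancels and a derivative-like Raman signature
    remains. Sign convention: ``laser2 - laser1``.
    """
    _require_common_axis("serds_difference", s1, s2)
    return s1.with_intensity(s2.intensity - s1.intensity, stage="serds_difference")


def average_grid(diffs: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of difference spectra over grid positions."""
    if len(diffs) == 0:
        raise PreprocessError("average_grid", "empty spectrum list")
    _require_common_axis("average_grid", *diffs)
    mean = np.mean([s.intensity for s in diffs], axis=0)
    return diffs[0].with_intensity(mean, stage="grid_mean")


def savgol_smooth(s: Spectrum, window: int = 11, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Edge policy: scipy's ``mode="interp"`` — a polynomial of the given order
    is fitted to the first/last window and evaluated at the edge points, so
    polynomials of degree <= ``polyorder`` are reproduced exactly everywhere.
    """
    if window % 2 == 0 or window <= polyorder:
        raise PreprocessError("savgol", f"window={window} must be odd and > polyorder={polyorder}")
    if window > len(s):
        raise PreprocessError("savgol", f"window={window} exceeds spectrum length {len(s)}")
    return s.with_intensity(
        savgol_filter(s.intensity, window, polyorder, mode="interp"), stage="savgol"
    )


def resample_uniform(s: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Linear interpolation onto the half-open uniform grid [start, stop).

    At defaults (350 to 2000 cm^-1, 1 cm^-1 step) the output has exactly
    1650 channels. The input axis must cover the target grid.
    """
    config = config or PreprocessConfig()
    grid = config.target_grid()
    if s.axis[0] > grid[0] or s.axis[-1] < grid[-1]:
        raise PreprocessError(
            "resample",
            f"input axis [{s.axis[0]:g}, {s.axis[-1]:g}] does not cover the "
            f"target grid [{grid[0]:g}, {grid[-1]:g}]",
        )
    return Spectrum(grid, np.interp(grid, s.axis, s.intensity), dict(s.meta, stage="resampled"))


def preprocess_sample(sample: RawSample, config: PreprocessConfig | None = None) -> Spectrum:
    """Full chain: one :class:`RawSample` to one model-input spectrum."""
    config = config or PreprocessConfig()
    per_channel = average_replicates(sample)
    n_grid = sample.measurements.shape[0]
    diffs = []
    for g in range(n_grid):
        c1, c2 = common_mode_rejection(per_channel[(g, 1)], per_channel[(g, 2)], config)
        diffs.append(serds_difference(c1, c2))
    pooled = average_grid(diffs)
    smoothed = savgol_smooth(pooled, config.sg_window, config.sg_polyorder)
    out = resample_uniform(smoothed, config)
    out.meta.update(sample_id=sample.sample_id, true_soc=sample.true_soc, stage="preprocessed")
    return out


def preprocess_dataset(
    samples: Sequence[RawSample], config: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess a dataset into a (samples x channels) matrix + SOC labels."""
    config = config or PreprocessConfig()
    spectra = [preprocess_sample(s, config) for s in samples]
    X = np.stack([sp.intensity for sp in spectra])
    y = np.array([s.true_soc for s in samples])
    return X, y


# ---------------------------------------------------------------------------
# writers: per-sample two-column text + dataset-level training matrix
# ---------------------------------------------------------------------------


def write_spectrum(s: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([s.axis, s.intensity]),
        delimiter=",",
        header="wavenumber,intensity",
        comments="",
    )
    return path


def write_dataset_matrix(
    X: np.ndarray, y: np.ndarray, path: str | Path, grid: np.ndarray | None = None
) -> Path:
    """Write a samples x channels matrix with the SOC label as last column."""
    path = Path(path)
    n_ch = X.shape[1]
    cols = (
        [f"w{g:g}" for g in grid] if grid is not None else [f"ch{i}" for i in range(n_ch)]
    )
    header = ",".join(cols + ["soc"])
    np.savetxt(path, np.column_stack([X, y]), delimiter=",", header=header, comments="")
    return path


def read_dataset_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return table[:, :-1], table[:, -1]
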