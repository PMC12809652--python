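"""Synthetic dual-laser SERDS soil-spectra generator.

Emulates the statistical structure of a shifted-excitation Raman measurement
campaign on soil: per sample, a small spatial grid of positions is measured
with two closely gapped lasers and several replicates per laser. Each raw
measurement is

    albedo * (fluorescence(SOC) + raman(SOC, laser)) + offset + noise

where the Raman component of laser 2 is the laser-1 component translated by
``laser_shift`` on the native wavenumber axis while the fluorescence
component is (near-)identical across the two lasers — the premise that makes
SERDS differencing remove fluorescence. A per-sample log-normal albedo
factor makes the spectrum -> SOC mapping weakly multimodal (soils with
different SOC can produce similar spectra), and label-conditional
heteroscedastic noise decouples the spectrum from the reported SOC label.

Everything is seeded: a config's seed fully determines the dataset. The
fluorescence shape, band list and noise defaults are documented stand-ins
chosen to be qualitatively realistic; no real soil library is emulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "SyntheticConfig",
    "RawSample",
    "RAMAN_BANDS",
    "SOC_SATURATION",
    "band_amplitude",
    "soc_to_raman",
    "fluorescence_background",
    "heteroscedastic_label_noise",
    "generate_dataset",
    "write_sample",
    "read_sample",
    "write_dataset",
    "read_dataset",
]

# Gaussian Raman bands standing in for organic-matter features:
# (center cm^-1, width cm^-1, relative amplitude). Centers loosely follow
# common soil/organic assignments (silicate ~465, phosphate ~960, carbonate
# ~1090, amorphous-carbon D/G-like ~1340/1590, CH2 ~1450, amide/C=C ~1660).
RAMAN_BANDS: tuple[tuple[float, float, float], ...] = (
    (465.0, 12.0, 0.35),
    (960.0, 10.0, 0.45),
    (1090.0, 12.0, 0.60),
    (1340.0, 25.0, 0.80),
    (1450.0, 18.0, 0.50),
    (1660.0, 22.0, 1.00),
)

# Band amplitudes grow with SOC but saturate (monotone, deliberately
# non-linear): amplitude_k(soc) = A_k * soc / (1 + soc / SOC_SATURATION).
SOC_SATURATION = 8.0


class SyntheticConfig(BaseModel):
    """Configuration of the synthetic SERDS campaign.

    Defaults are the desk-scale study conditions: 300 samples on a 3x3 grid
    with 3 replicates per laser. ``full_scale()`` returns the full-scale
    preset (10x10 grid, 15 replicates).
    """

    model_config = ConfigDict(extra="forbid")

    n_samples: int = 300
    soc_range: tuple[float, float] = (0.28, 6.95)
    grid_shape: tuple[int, int] = (3, 3)
    n_replicates: int = 3
    laser_shift: float = 10.0  # cm^-1 gap between the two excitations
    fluorescence_amplitude_ratio: float = 50.0  # fluorescence : Raman scale; 0 = off
    heteroscedastic_coeffs: tuple[float, float] = (0.1, 0.05)  # sd(soc) = c0 + c1*soc, in % SOC
    albedo_sd: float = 0.2  # sd of log albedo factor
    integration_time: float = 0.2  # seconds
    replicate_noise_sd: float = 0.02  # additive intensity noise per replicate
    offset_sd: float = 0.02  # per-measurement additive baseline offset sd
    fluor_laser_perturbation: float = 0.01  # relative fluorescence mismatch between lasers
    axis_start: float = 330.0  # native wavenumber axis (cm^-1)
    axis_stop: float = 2030.0
    axis_step: float = 1.0
    seed: int = 0

    @field_validator("n_samples", "n_replicates")
    @classmethod
    def _positive_count(cls, v: int, info) -> int:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @field_validator("grid_shape")
    @classmethod
    def _grid_positive(cls, v: tuple[int, int]) -> tuple[int, int]:
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("grid_shape entries must be positive")
        return v

    @field_validator("soc_range")
    @classmethod
    def _soc_range_valid(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0.0 < lo < hi < 100.0):
            raise ValueError("soc_range must satisfy 0 < min < max < 100 (% by mass)")
        return v

    @field_validator(
        "fluorescence_amplitude_ratio", "albedo_sd", "replicate_noise_sd", "offset_sd"
    )
    @classmethod
    def _nonnegative(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @field_validator("integration_time", "laser_shift", "axis_step")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "SyntheticConfig":
        if self.axis_stop <= self.axis_start:
            raise ValueError("axis_stop must exceed axis_start")
        c0, c1 = self.heteroscedastic_coeffs
        lo, hi = self.soc_range
        # sd(soc) is affine, so positivity at both endpoints covers the range
        if c0 + c1 * lo <= 0 or c0 + c1 * hi <= 0:
            raise ValueError(
                "heteroscedastic_coeffs must give sd > 0 over soc_range "
                f"(got sd({lo})={c0 + c1 * lo:.4g}, sd({hi})={c0 + c1 * hi:.4g})"
            )
        return self

    @classmethod
    def full_scale(cls, **overrides: Any) -> "SyntheticConfig":
        """Full-scale preset: 10x10 grid, 15 replicates, 200 ms integration."""
        base: dict[str, Any] = dict(
            n_samples=901, grid_shape=(10, 10), n_replicates=15, integration_time=0.2
        )
        base.update(overrides)
        return cls(**base)

    def native_axis(self) -> np.ndarray:
        return np.arange(self.axis_start, self.axis_stop + 0.5 * self.axis_step, self.axis_step)


@dataclass
class RawSample:
    """One synthetic soil sample.

    ``measurements`` is indexed ``(grid_position, laser, replicate)`` and
    holds intensity vectors on the shared native ``axis``.
    """

    sample_id: str
    true_soc: float
    measurements: np.ndarray  # shape (n_grid, 2, n_replicates, n_channels)
    axis: np.ndarray
    integration_time: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.measurements = np.asarray(self.measurements, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.measurements.ndim != 4 or self.measurements.shape[1] != 2:
            raise ValueError(
                "measurements must have shape (n_grid, 2 lasers, n_replicates, n_channels)"
            )
        if self.measurements.shape[-1] != self.axis.size:
            raise ValueError("measurement vectors must match the native axis length")
        if not np.all(np.isfinite(self.measurements)):
            raise ValueError("intensities must be finite")

    @property
    def n_grid(self) -> int:
        return self.measurements.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.measurements.shape[2]


def band_amplitude(soc: float, base_amplitude: float) -> float:
    """Amplitude of one Raman band: ``A * soc / (1 + soc / SOC_SATURATION)``.

    Monotone increasing in SOC but saturating, so spectrum amplitude is
    deliberately not proportional to the label.
    """
    return base_amplitude * soc / (1.0 + soc / SOC_SATURATION)


def soc_to_raman(soc: float, axis: np.ndarray) -> np.ndarray:
    """SOC-dependent Raman component: sum of fixed Gaussian bands.

    Raises ``ValueError`` for negative SOC. ``soc=0`` gives all zeros.
    """
    if soc < 0:
        raise ValueError(f"soc must be >= 0, got {soc}")
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    for center, width, amp in RAMAN_BANDS:
        out += band_amplitude(soc, amp) * np.exp(-0.5 * ((axis - center) / width) ** 2)
    return out


def fluorescence_background(
    soc: float, axis: np.ndarray, amplitude_ratio: float
) -> np.ndarray:
    """Smooth fluorescence background (broad hump + gentle linear ramp).

    The amplitude scales with ``amplitude_ratio`` (fluorescence:Raman scale)
    and grows mildly with SOC — organic matter fluoresces — which couples the
    dominant background to the confounded quantity of interest.
    """
    axis = np.asarray(axis, dtype=float)
    shape = 0.5 + 0.5 * np.exp(-(((axis - 1150.0) / 450.0) ** 2)) + 1.5e-4 * (2000.0 - axis)
    amp = amplitude_ratio * (0.5 + 0.5 * soc / (1.0 + soc / SOC_SATURATION))
    return amp * shape


def heteroscedastic_label_noise(soc: float, coeffs: Sequence[float]) -> float:
    """Label-conditional noise sd: ``sd(soc) = c0 + c1 * soc`` (% SOC).

    Monotone in SOC for ``c1 >= 0``. Raises if the sd is non-positive.
    """
    c0, c1 = coeffs
    sd = c0 + c1 * soc
    if sd <= 0:
        raise ValueError(f"noise sd must be positive, got {sd} at soc={soc}")
    return float(sd)


def _sample_streams(seed: int, n_samples: int):
    """Independent child generators (labels, label noise, albedo, intensity noise)."""
    ss = np.random.SeedSequence(seed)
    labels, label_noise, albedo, meas_noise = ss.spawn(4)
    return (
        np.random.default_rng(labels),
        np.random.default_rng(label_noise),
        np.random.default_rng(albedo),
        np.random.default_rng(meas_noise),
    )


def generate_dataset(
    config: SyntheticConfig, soc_values: Sequence[float] | None = None
) -> list[RawSample]:
    """Generate a seeded synthetic dataset.

    SOC labels are drawn uniformly over ``config.soc_range`` unless explicit
    ``soc_values`` are supplied (useful for controlled experiments, e.g.
    duplicated labels). The config seed fully determines the output.
    """
    axis = config.native_axis()
    n_grid = config.grid_shape[0] * config.grid_shape[1]
    rng_lab, rng_lnoise, rng_alb, rng_noise = _sample_streams(config.seed, config.n_samples)

    lo, hi = config.soc_range
    if soc_values is None:
        soc = rng_lab.uniform(lo, hi, size=config.n_samples)
    else:
        soc = np.asarray(soc_values, dtype=float)
        if soc.size != config.n_samples:
            raise ValueError(
                f"soc_values length {soc.size} != n_samples {config.n_samples}"
            )
        if np.any(soc < lo) or np.any(soc > hi):
            raise ValueError("soc_values must lie within soc_range")

    # label-conditional heteroscedastic perturbation: the spectrum reflects an
    # effective SOC that differs from the reported label
    c0, c1 = config.heteroscedastic_coeffs
    sd = c0 + c1 * soc
    soc_spec = np.clip(soc + rng_lnoise.normal(size=config.n_samples) * sd, 1e-6, None)
    albedo = np.exp(rng_alb.normal(0.0, config.albedo_sd, size=config.n_samples))

    # laser-2 fluorescence differs from laser-1 by a small smooth relative tilt
    mid = 0.5 * (axis[0] + axis[-1])
    tilt = 1.0 + config.fluor_laser_perturbation * (axis - mid) / (axis[-1] - axis[0])

    samples: list[RawSample] = []
    for i in range(config.n_samples):
        fluor1 = fluorescence_background(soc_spec[i], axis, config.fluorescence_amplitude_ratio)
        clean = np.stack(
            [
                fluor1 + soc_to_raman(soc_spec[i], axis),
                fluor1 * tilt + soc_to_raman(soc_spec[i], axis - config.laser_shift),
            ]
        )  # (2, L)
        shape = (n_grid, 2, config.n_replicates)
        offsets = rng_noise.normal(0.0, config.offset_sd, size=shape)[..., None]
        noise = rng_noise.normal(0.0, config.replicate_noise_sd, size=shape + (axis.size,))
        meas = albedo[i] * clean[None, :, None, :] + offsets + noise
        samples.append(
            RawSample(
                sample_id=f"syn-{config.seed}-{i:04d}",
                true_soc=float(soc[i]),
                measurements=meas,
                axis=axis,
                integration_time=config.integration_time,
                meta={
                    "albedo": float(albedo[i]),
                    "soc_spectral": float(soc_spec[i]),
                    "grid_shape": list(config.grid_shape),
                },
            )
        )
    return samples


# ---------------------------------------------------------------------------
# on-disk container: one CSV per sample (first column wavenumber, one column
# per (grid, laser, replicate) measurement) + JSON metadata sidecar, and a
# dataset-level manifest listing all samples
# ---------------------------------------------------------------------------


def _column_names(sample: RawSample) -> list[str]:
    g, _, r, _ = sample.measurements.shape
    return [f"g{i}_l{l}_r{k}" for i in range(g) for l in (1, 2) for k in range(r)]


def write_sample(sample: RawSample, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g, _, r, L = sample.measurements.shape
    flat = sample.measurements.reshape(g * 2 * r, L)
    table = np.column_stack([sample.axis, flat.T])
    csv_path = directory / f"{sample.sample_id}.csv"
    header = ",".join(["wavenumber"] + _column_names(sample))
    np.savetxt(csv_path, table, delimiter=",", header=header, comments="")
    sidecar = {
        "sample_id": sample.sample_id,
        "true_soc": sample.true_soc,
        "integration_time": sample.integration_time,
        "shape": list(sample.measurements.shape),
        "index_order": "(grid_position, laser, replicate)",
        "meta": sample.meta,
    }
    (directory / f"{sample.sample_id}.json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_sample(directory: str | Path, sample_id: str) -> RawSample:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{sample_id}.json").read_text())
    table = np.loadtxt(directory / f"{sample_id}.csv", delimiter=",", skiprows=1)
    axis = table[:, 0]
    shape = tuple(sidecar["shape"])
    meas = table[:, 1:].T.reshape(shape)
    return RawSample(
        sample_id=sidecar["sample_id"],
        true_soc=sidecar["true_soc"],
        measurements=meas,
        axis=axis,
        integration_time=sidecar["integration_time"],
        meta=sidecar.get("meta", {}),
    )


def write_dataset(
    samples: Sequence[RawSample], directory: str | Path, config: SyntheticConfig | None = None
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in samples:
        write_sample(s, directory)
    manifest = {
        "sample_ids": [s.sample_id for s in samples],
        "n_samples": len(samples),
        "generator_config": config.model_dump() if config is not None else None,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_dataset(directory: str | Path) -> list[RawSample]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [read_sample(directory, sid) for sid in manifest["sample_ids"]]
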