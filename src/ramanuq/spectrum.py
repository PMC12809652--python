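"""Core spectral container.

A :class:`Spectrum` is a wavenumber axis (cm^-1, strictly increasing) paired
with an intensity vector of the same length, plus free-form provenance
metadata (sample id, processing stage, ...). All preprocessing stages consume
and produce this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Spectrum"]


@dataclass
class Spectrum:
    """One spectrum on an explicit wavenumber axis.

    Parameters
    ----------
    axis:
        Wavenumber values in cm^-1, strictly increasing.
    intensity:
        Intensities (arbitrary units), same length as ``axis``.
    meta:
        Provenance labels, e.g. ``{"sample_id": ..., "stage": ...}``.
    """

    axis: np.ndarray
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis and intensity must be 1-D")
        if self.axis.shape != self.intensity.shape:
            raise ValueError(
                f"axis length {self.axis.size} != intensity length {self.intensity.size}"
            )
        if not np.all(np.isfinite(self.axis)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("axis and intensity must be finite")
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return self.axis.size

    def with_intensity(self, intensity: np.ndarray, stage: str | None = None) -> "Spectrum":
        """Return a new Spectrum on the same axis, optionally tagging the stage."""
        meta = dict(self.meta)
        if stage is not None:
            meta["stage"] = stage
        return Spectrum(self.axis.copy(), np.asarray(intensity, dtype=float), meta)

    def same_axis(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return self.axis.shape == other.axis.shape and np.allclose(
            self.axis, other.axis, atol=atol, rtol=0.0
        )
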