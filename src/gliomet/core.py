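"""Shared domain types for the gliomet pipeline.

The containers here are deliberately thin: numpy arrays plus the acquisition
and geometry metadata that downstream operations need (echo time for the
signal-to-concentration conversion, voxel spacing for physical-distance
morphology, frame times for integrals). Validation happens at construction
so that every operation can assume a well-formed object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionParams",
    "DscSeries",
    "ParametricMap",
    "RegionMask",
    "ConcentrationCurve",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """MRI acquisition parameters of the DSC and DWI protocols.

    Defaults follow a 1.5 T gradient-echo EPI perfusion protocol
    (TR/TE = 1490/40 ms, 50 dynamic frames with at least five pre-bolus
    baseline frames) and a three-point diffusion acquisition with
    b = 0, 500, 1000 s/mm^2.
    """

    te_seconds: float = 0.040
    tr_seconds: float = 1.49
    n_timepoints: int = 50
    n_baseline: int = 8
    b_values: tuple[float, ...] = (0.0, 500.0, 1000.0)

    def __post_init__(self) -> None:
        if not self.te_seconds > 0:
            raise ValueError("te_seconds must be > 0")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be > 0")
        if self.n_baseline < 5:
            raise ValueError(
                "n_baseline must be >= 5 (at least five pre-bolus frames)"
            )
        if self.n_baseline >= self.n_timepoints:
            raise ValueError("n_baseline must be < n_timepoints")
        bvals = tuple(float(b) for b in self.b_values)
        if 0.0 not in bvals or len(set(bvals)) < 2:
            raise ValueError("b_values must contain 0 and >= 2 distinct values")
        object.__setattr__(self, "b_values", bvals)

    @property
    def times(self) -> np.ndarray:
        """Frame mid-times in seconds, uniform at TR spacing from t = 0."""
        return np.arange(self.n_timepoints, dtype=float) * self.tr_seconds


@dataclass
class DscSeries:
    """A 4D dynamic susceptibility contrast signal volume (x, y, z, t)."""

    signal: np.ndarray
    times: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, t)")
        if self.signal.shape[-1] != self.times.size:
            raise ValueError("time axis length must match times")
        if self.times.size != self.acq.n_timepoints:
            raise ValueError("times length must equal acq.n_timepoints")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly ascending")
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValueError("times must be uniformly spaced (1e-6 relative)")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValueError("signal must be finite and non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class ParametricMap:
    """A 3D scalar map (ADC in mm^2/s, CBV/rCBV as dimensionless ratios).

    Invalid voxels (e.g. non-positive signal during fitting) are NaN and are
    excluded from all VOI statistics.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive values")


MASK_LABELS = (
    "lesion",
    "necrotic_core",
    "edema",
    "perilesional_ring",
    "residual_edema",
    "reference",
    "arterial",
    "enhancing",
)


@dataclass
class RegionMask:
    """A labeled boolean 3D region mask sharing the grid of its maps."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    label: str = "lesion"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive values")
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def __bool__(self) -> bool:  # non-empty test
        return bool(self.voxels.any())


@dataclass
class ConcentrationCurve:
    """A tracer concentration-time curve in dR2* units (1/s)."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 1 or self.values.shape != self.times.shape:
            raise ValueError("values and times must be 1D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])
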