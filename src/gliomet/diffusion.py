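"""ADC mapping from multi-b diffusion-weighted volumes.

The apparent diffusion coefficient is obtained voxel-wise by ordinary least
squares of ln S(b) against b: S(b) = S(0)*exp(-b*ADC), so ADC is minus the
slope of the log-signal, in mm^2/s. With the three-point acquisition
(b = 0, 500, 1000 s/mm^2) and noiseless mono-exponential signals the fit is
exact. A signal-weighted variant is available; with only a few b-values the
two differ negligibly.

ADC is carried in mm^2/s throughout the package; the conventional x10^-3
display scaling is applied only at the CSV/report layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParametricMap

__all__ = ["DwiStack", "fit_adc_map"]


@dataclass
class DwiStack:
    """One 3D volume per diffusion weighting b (s/mm^2)."""

    volumes: np.ndarray  # (n_b, x, y, z)
    b_values: tuple[float, ...]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be (n_b, x, y, z)")
        self.b_values = tuple(float(b) for b in self.b_values)
        if self.volumes.shape[0] != len(self.b_values):
            raise ValueError("one volume per b-value required")
        if 0.0 not in self.b_values or len(set(self.b_values)) < 2:
            raise ValueError("b_values must contain 0 and >= 2 distinct values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)


def fit_adc_map(stack: DwiStack, weighted: bool = False) -> ParametricMap:
    """Fit ADC per voxel from ln S(b) vs b; ADC = -slope (mm^2/s).

    Voxels with any non-positive signal (log undefined) are marked invalid
    (NaN) rather than raising. ``weighted=True`` weights each b-value's
    log-signal by the squared signal, the usual variance-stabilizing scheme.
    """
    b = np.asarray(stack.b_values, dtype=float)[:, None]
    vols = stack.volumes.reshape(len(stack.b_values), -1)
    valid = (vols > 0).all(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(vols)
    if weighted:
        w = vols**2
    else:
        w = np.ones_like(vols)
    # per-voxel weighted least squares slope of logs against b
    with np.errstate(divide="ignore", invalid="ignore"):
        wsum = w.sum(axis=0)
        b_bar = (w * b).sum(axis=0) / wsum
        y_bar = (w * logs).sum(axis=0) / wsum
        cov = (w * (b - b_bar) * (logs - y_bar)).sum(axis=0)
        var = (w * (b - b_bar) ** 2).sum(axis=0)
        slope = cov / var
    adc = np.where(valid & (var > 0), -slope, np.nan)
    return ParametricMap(
        values=adc.reshape(stack.volumes.shape[1:]),
        spacing_mm=stack.spacing_mm,
        name="adc",
    )
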