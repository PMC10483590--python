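"""Pixel-level detector noise model and propagation to integrated intensities.

The variance of a detector pixel with count c is modelled as

    var(c) = gamma * G * c + psi

where G is the detector gain (counts per incident electron), gamma >= 1 a
cascade factor inflating the Poisson variance, and psi the variance of a
dark-image pixel.  Summing a peak region S and subtracting the rim-estimated
background b_bar propagates to the integrated-intensity variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["NoiseParams", "PeakRegion", "pixel_variance", "integrate_peak"]


@dataclass(frozen=True)
class NoiseParams:
    """Detector noise parameters (gain G, cascade factor gamma, pixel factor psi)."""

    G: float = 1.0
    gamma: float = 1.0
    psi: float = 0.0

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("gain G must be positive")
        if self.gamma < 1:
            raise ValueError("cascade factor gamma must be >= 1")
        if self.psi < 0:
            raise ValueError("pixel factor psi must be non-negative")


@dataclass
class PeakRegion:
    """Pixel counts of a peak region S and of the background rim around it."""

    peak_counts: Sequence[float]
    rim_counts: Sequence[float]

    def __post_init__(self) -> None:
        self.peak_counts = np.asarray(self.peak_counts, dtype=float)
        self.rim_counts = np.asarray(self.rim_counts, dtype=float)
        if self.peak_counts.size < 1:
            raise ValueError("peak region must contain at least one pixel")
        if self.rim_counts.size < 1:
            raise ValueError("rim must contain at least one pixel (no background estimate)")
        if (self.peak_counts < 0).any() or (self.rim_counts < 0).any():
            raise ValueError("pixel counts must be non-negative")


def pixel_variance(c, params: NoiseParams):
    """Variance of a detector pixel with count(s) c: gamma*G*c + psi."""
    c = np.asarray(c, dtype=float)
    if (c < 0).any():
        raise ValueError("pixel count must be non-negative")
    out = params.gamma * params.G * c + params.psi
    return float(out) if out.ndim == 0 else out


def integrate_peak(region: PeakRegion, params: NoiseParams) -> tuple[float, float]:
    """Background-corrected integrated intensity and its e.s.u.

    I = sum_S c_i - n_S * b_bar with b_bar the unweighted rim mean;
    Var(I) = sum_S var(c_i) + (n_S/n_rim)^2 * sum_rim var(c_j).
    """
    peak = np.asarray(region.peak_counts, dtype=float)
    rim = np.asarray(region.rim_counts, dtype=float)
    n_s, n_rim = peak.size, rim.size
    b_bar = rim.mean()
    intensity = float(peak.sum() - n_s * b_bar)
    var = float(
        pixel_variance(peak, params).sum()
        + (n_s / n_rim) ** 2 * pixel_variance(rim, params).sum()
    )
    return intensity, float(np.sqrt(var))
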