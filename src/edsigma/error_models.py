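"""The four e.s.u. models for reflection intensities.

* model 0 — counting-statistics e.s.u.'s, unchanged;
* model 1 — sample standard deviation of the symmetry-equivalent intensities
  (Bessel-corrected), with a binned lookup table for reflections measured once;
* model 2 — three-parameter correction (s_fac, s_B, s_add) of the counting
  e.s.u., referenced to the group mean intensity;
* model 3 — the same correction referenced to the largest intensity among the
  symmetry equivalents, which avoids over-inflating the e.s.u.'s of strong
  reflections when the within-group spread is large.

The corrected e.s.u. follows the SDFAC/SDB/SDADD convention:

    sigma' = s_fac * sqrt(sigma^2 + s_B * max(I_ref, 0) + (s_add * I_ref)^2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reflection_data import ReflectionGroup

__all__ = [
    "ErrorModelParams",
    "LookupTable",
    "sample_std",
    "build_lookup_table",
    "model1_assign",
    "corrected_sigma",
    "apply_error_model",
]

RESOLUTION_BIN_WIDTH = 0.2  # 1/Angstrom
N_INTENSITY_BINS = 10


@dataclass(frozen=True)
class ErrorModelParams:
    """Correction triple: scale s_fac, intensity-linear s_B, fractional s_add.

    s_fac rescales the whole uncertainty (absorbing e.g. detector-gain error);
    s_B (counts) adds variance proportional to the intensity (instrumental
    instabilities); s_add (dimensionless) adds variance proportional to the
    squared intensity and has no direct physical interpretation.
    """

    s_fac: float = 1.0
    s_b: float = 0.0
    s_add: float = 0.0

    def __post_init__(self) -> None:
        if not self.s_fac > 0:
            raise ValueError("s_fac must be positive")
        if not (math.isfinite(self.s_b) and math.isfinite(self.s_add)):
            raise ValueError("s_B and s_add must be finite")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.s_fac, self.s_b, self.s_add)


def sample_std(values: Sequence[float]) -> float:
    """Bessel-corrected sample standard deviation, sqrt(sum (x-mean)^2/(n-1))."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("sample_std requires at least two values")
    return float(np.std(values, ddof=1))


@dataclass
class LookupTable:
    """(intensity bin x resolution bin) table of mean e.s.u.'s for n=1 reflections.

    Intensity bins are ten equal-count bins of the multiply-measured
    reflections sorted by intensity (the remainder N mod 10 is spread one per
    bin from the strongest bin downward); resolution bins have fixed width
    0.2 1/Angstrom anchored at d* = 0.
    """

    intensity_edges: np.ndarray  # 9 interior thresholds separating the 10 bins
    cells: dict[tuple[int, int], float]
    global_mean: float

    def intensity_bin(self, intensity: float) -> int:
        return int(np.searchsorted(self.intensity_edges, intensity, side="right"))

    @staticmethod
    def resolution_bin(d_star: float) -> int:
        return int(d_star // RESOLUTION_BIN_WIDTH)

    def lookup(self, intensity: float, d_star: float) -> float:
        """Cell e.s.u.; falls back to the nearest non-empty resolution bin of the
        same intensity bin, then to the global mean."""
        ibin = self.intensity_bin(intensity)
        rbin = self.resolution_bin(d_star)
        if (ibin, rbin) in self.cells:
            return self.cells[(ibin, rbin)]
        candidates = [r for (i, r) in self.cells if i == ibin]
        if candidates:
            nearest = min(candidates, key=lambda r: (abs(r - rbin), r))
            return self.cells[(ibin, nearest)]
        return self.global_mean


def build_lookup_table(groups: Sequence[ReflectionGroup]) -> LookupTable:
    """Build the model-1 lookup table from groups with n >= 2.

    Each multi-member group contributes one entry (its mean intensity, its
    sample-standard-deviation e.s.u., its resolution); every cell stores the
    arithmetic mean of the e.s.u.'s of its members.
    """
    entries = []
    for g in groups:
        if g.n >= 2:
            if g.d_star is None:
                raise ValueError(f"group {g.canonical_hkl} lacks resolution (d*) information")
            entries.append((g.mean_intensity, g.sample_std, g.d_star))
    if not entries:
        raise ValueError("model 1 inapplicable: no group has n >= 2")

    entries.sort(key=lambda t: t[0])
    n = len(entries)
    base, rem = divmod(n, N_INTENSITY_BINS)
    sizes = [base] * N_INTENSITY_BINS
    for j in range(rem):  # remainder one-per-bin from the highest bin downward
        sizes[N_INTENSITY_BINS - 1 - j] += 1

    intens = np.array([e[0] for e in entries])
    bounds = np.cumsum(sizes)[:-1]
    # threshold between bin b and b+1: first intensity of bin b+1
    edges = np.array([intens[min(b, n - 1)] for b in bounds])

    cells_acc: dict[tuple[int, int], list[float]] = {}
    start = 0
    for ibin, size in enumerate(sizes):
        for mean_i, esu, ds in entries[start : start + size]:
            rbin = LookupTable.resolution_bin(ds)
            cells_acc.setdefault((ibin, rbin), []).append(esu)
        start += size
    cells = {key: float(np.mean(vals)) for key, vals in cells_acc.items()}
    global_mean = float(np.mean([e[1] for e in entries]))
    return LookupTable(edges, cells, global_mean)


def model1_assign(
    groups: Sequence[ReflectionGroup], table: LookupTable | None = None
) -> list[ReflectionGroup]:
    """Assign model-1 e.s.u.'s: group sample std for n >= 2, table lookup for n=1."""
    if table is None:
        table = build_lookup_table(groups)
    out = []
    for g in groups:
        gc = g.copy()
        if gc.n >= 2:
            esu = gc.sample_std
            for m in gc.members:
                m.sigma = esu
        else:
            m = gc.members[0]
            if m.d_star is None:
                raise ValueError(f"singleton {gc.canonical_hkl} lacks d* for table lookup")
            m.sigma = table.lookup(m.intensity, m.d_star)
        out.append(gc)
    return out


def corrected_sigma(sigma, i_ref, params: ErrorModelParams):
    """Three-parameter corrected e.s.u.

    sigma' = s_fac * sqrt(sigma^2 + s_B * max(I_ref, 0) + (s_add * I_ref)^2).
    Negative reference intensities contribute nothing to the linear term so
    the variance stays positive.  Accepts scalars or arrays.
    """
    sigma = np.asarray(sigma, dtype=float)
    i_ref = np.asarray(i_ref, dtype=float)
    if (sigma < 0).any():
        raise ValueError("sigma must be non-negative")
    var = sigma**2 + params.s_b * np.maximum(i_ref, 0.0) + (params.s_add * i_ref) ** 2
    if (var < 0).any():
        raise ValueError("error-model parameters yield negative variance")
    out = params.s_fac * np.sqrt(var)
    return float(out) if out.ndim == 0 else out


def apply_error_model(
    groups: Sequence[ReflectionGroup],
    model: int,
    params: ErrorModelParams | None = None,
    table: LookupTable | None = None,
) -> list[ReflectionGroup]:
    """Return new groups with per-measurement e.s.u.'s set by the chosen model.

    Intensities are never modified.  For models 2/3, singleton groups use
    their own intensity as the reference (mean and max coincide).
    """
    if model == 0:
        return [g.copy() for g in groups]
    if model == 1:
        return model1_assign(groups, table)
    if model in (2, 3):
        if params is None:
            raise ValueError(f"model {model} requires ErrorModelParams")
        out = []
        for g in groups:
            gc = g.copy()
            i_ref = gc.mean_intensity if model == 2 else gc.max_intensity
            for m in gc.members:
                m.sigma = corrected_sigma(m.sigma, i_ref, params)
            out.append(gc)
        return out
    raise ValueError(f"unknown error model {model!r} (expected 0, 1, 2 or 3)")
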