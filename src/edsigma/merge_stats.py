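"""Merging of symmetry equivalents and standard data-quality statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reflection_data import ReflectionGroup

__all__ = [
    "MergedReflection",
    "StatsConfig",
    "merge_groups",
    "r_int",
    "r_factors",
    "multiplicity_histogram",
]


@dataclass
class StatsConfig:
    """Observed criterion and refinement-weight instability factor.

    ``u`` enters the weights w = 1/(sigma^2(Fo^2) + (u*Fo^2)^2);
    ``obs_threshold`` is the multiplier in the observed criterion I > t*sigma.
    """

    u: float = 0.01
    obs_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.u < 0:
            raise ValueError("instability factor u must be non-negative")
        if self.obs_threshold <= 0:
            raise ValueError("obs_threshold must be positive")


@dataclass
class MergedReflection:
    """Unique reflection after averaging equivalents."""

    hkl: tuple[int, int, int]
    intensity: float
    sigma: float
    n: int
    observed: bool


def merge_groups(
    groups: Sequence[ReflectionGroup],
    cfg: StatsConfig | None = None,
    use_scatter: bool = False,
) -> list[MergedReflection]:
    """Average each group of equivalents into one unique reflection.

    Intensity is the unweighted mean; the merged e.s.u. is the standard error
    propagated from the member e.s.u.'s, sqrt(sum sigma'^2)/n.  With
    ``use_scatter`` the propagated value is floored by the scatter-based
    standard error of the mean, s_h/sqrt(n).
    """
    if not groups:
        raise ValueError("no groups to merge")
    cfg = cfg or StatsConfig()
    merged = []
    for g in groups:
        mean = g.mean_intensity
        sig = float(np.sqrt(np.sum(g.sigmas**2)) / g.n)
        if use_scatter and g.n >= 2:
            sig = max(sig, g.sample_std / np.sqrt(g.n))
        if sig <= 0:
            raise ValueError(f"non-positive merged e.s.u. for {g.canonical_hkl}")
        merged.append(
            MergedReflection(
                hkl=g.canonical_hkl,
                intensity=mean,
                sigma=sig,
                n=g.n,
                observed=mean > cfg.obs_threshold * sig,
            )
        )
    return merged


def r_int(groups: Sequence[ReflectionGroup]) -> float:
    """Internal merging residual in percent.

    R_int = 100 * sum_h sum_l |I_hl - <I>_h| / sum_h sum_l I_hl over groups
    with n >= 2.
    """
    num = 0.0
    den = 0.0
    any_multi = False
    for g in groups:
        if g.n < 2:
            continue
        any_multi = True
        ints = g.intensities
        num += float(np.abs(ints - ints.mean()).sum())
        den += float(ints.sum())
    if not any_multi:
        raise ValueError("R_int undefined: no group has n >= 2")
    if den <= 0:
        raise ValueError("R_int undefined: non-positive intensity sum")
    return 100.0 * num / den


def r_factors(
    fo2: Sequence[float],
    fc2: Sequence[float],
    sig_fo2: Sequence[float],
    cfg: StatsConfig | None = None,
    n_par: int = 0,
) -> tuple[float, float, float]:
    """R_obs (%), wR_all (%) and goodness of fit.

    R_obs = sum ||Fo| - |Fc|| / sum |Fo| over observed reflections
    (Fo^2 > threshold * sigma); wR_all = sqrt(sum w (Fo^2-Fc^2)^2 /
    sum w (Fo^2)^2) over all reflections with w = 1/(sigma^2 + (u*Fo^2)^2);
    GOF = sqrt(sum w (Fo^2-Fc^2)^2 / (N - n_par)).
    """
    cfg = cfg or StatsConfig()
    fo2 = np.asarray(fo2, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    sig = np.asarray(sig_fo2, dtype=float)
    if not (fo2.shape == fc2.shape == sig.shape):
        raise ValueError("Fo^2, Fc^2 and sigma arrays must have equal length")
    if (sig <= 0).any():
        raise ValueError("sigma(Fo^2) must be positive")

    obs = fo2 > cfg.obs_threshold * sig
    if obs.any():
        fo = np.sqrt(np.maximum(fo2[obs], 0.0))
        fc = np.sqrt(np.maximum(fc2[obs], 0.0))
        r_obs = 100.0 * np.abs(fo - fc).sum() / fo.sum()
    else:
        r_obs = float("nan")

    w = 1.0 / (sig**2 + (cfg.u * fo2) ** 2)
    chi2 = float(np.sum(w * (fo2 - fc2) ** 2))
    wr_all = 100.0 * np.sqrt(chi2 / np.sum(w * fo2**2))
    if fo2.size <= n_par:
        raise ValueError("GOF undefined: N_all <= N_par")
    gof = np.sqrt(chi2 / (fo2.size - n_par))
    return float(r_obs), float(wr_all), float(gof)


def multiplicity_histogram(groups: Sequence[ReflectionGroup]) -> dict[int, int]:
    """Count unique reflections by multiplicity n."""
    if not groups:
        raise ValueError("no groups")
    hist: dict[int, int] = {}
    for g in groups:
        hist[g.n] = hist.get(g.n, 0) + 1
    return dict(sorted(hist.items()))
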