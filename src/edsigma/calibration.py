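"""Normal-probability-plot calibration of the three-parameter error model.

The normalized deviation of measurement l of unique reflection h is

    delta_hl = (I_hl - <I>_h) / sigma'_hl

with <I>_h the (inclusive, by default) mean over the symmetry-equivalent
measurements and sigma' the corrected e.s.u.  If the e.s.u.'s are correct the
deltas follow a standard normal distribution, so the sorted deltas plotted
against the theoretical normal quantiles fall on the identity line.  The
correction parameters (s_fac, s_B, s_add) are fitted by minimizing

    D = sum_i (delta_(i) - q_i)^2

with re-sorting supercycles (after each inner minimization the deltas are
re-sorted against the fixed quantiles — by the rearrangement inequality the
re-sort can only decrease D).  Model 2 references the sigma' correction to the
group mean; model 3 to the largest symmetry-equivalent intensity.  Gross
outliers are removed by iterating the fit with Tukey's quartile fences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .error_models import ErrorModelParams, corrected_sigma
from .reflection_data import ReflectionGroup

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationConfig",
    "CalibrationResult",
    "reference_intensity",
    "normalized_deviations",
    "theoretical_quantiles",
    "fit_error_model",
    "tukey_outliers",
    "calibrate",
]


@dataclass
class CalibrationConfig:
    """Knobs of the calibration procedure.

    ``reference_mode`` selects the mean convention for the delta numerator
    (the inclusive mean gives singletons delta = 0 and is the default);
    ``tukey_k`` the fence multiplier; ``plotting_position`` the rank-to-CDF
    rule ("centered" = (i-1/2)/N, "expected" = i/(N+1)).
    """

    reference_mode: str = "inclusive_mean"
    tukey_k: float = 1.5
    plotting_position: str = "centered"
    init_params: ErrorModelParams = field(default_factory=ErrorModelParams)
    tol: float = 1e-8
    param_tol: float = 1e-6
    max_supercycles: int = 50
    max_outlier_iters: int = 20
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.tukey_k <= 0:
            raise ValueError("tukey_k must be positive")
        if self.max_supercycles < 1 or self.max_outlier_iters < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class CalibrationResult:
    """Fitted parameters and the final state of the normal probability plot."""

    params: ErrorModelParams
    deltas_sorted: np.ndarray
    quantiles: np.ndarray
    D: float
    slope: float
    intercept: float
    outlier_flags: np.ndarray  # per measurement, flat group/member order
    n_supercycles: int
    n_outlier_iters: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "params": {
                "s_fac": self.params.s_fac,
                "s_b": self.params.s_b,
                "s_add": self.params.s_add,
            },
            "D": self.D,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_points": int(len(self.deltas_sorted)),
            "n_outliers": int(np.sum(self.outlier_flags)),
            "n_supercycles": self.n_supercycles,
            "n_outlier_iters": self.n_outlier_iters,
            "converged": bool(self.converged),
        }


# ---------------------------------------------------------------------------
# Reference intensities and normalized deviations
# ---------------------------------------------------------------------------

def reference_intensity(
    group: ReflectionGroup,
    member_index: int | None = None,
    mode: str = "inclusive_mean",
    esus: Sequence[float] | None = None,
) -> float | None:
    """Reference intensity of a group member under a mean convention.

    ``exclusive_mean`` (mean over the other members) is undefined for n=1 and
    returns None; ``weighted_mean`` uses inverse-variance weights from the
    current e.s.u.'s (``esus`` or the stored member sigmas).
    """
    ints = group.intensities
    if mode == "inclusive_mean":
        return float(ints.mean())
    if mode == "max":
        return float(ints.max())
    if mode == "exclusive_mean":
        if member_index is None:
            raise ValueError("exclusive_mean requires a member index")
        if group.n == 1:
            return None
        mask = np.ones(group.n, dtype=bool)
        mask[member_index] = False
        return float(ints[mask].mean())
    if mode == "weighted_mean":
        s = np.asarray(esus, dtype=float) if esus is not None else group.sigmas
        w = 1.0 / s**2
        return float(np.sum(w * ints) / np.sum(w))
    raise ValueError(f"unknown reference mode {mode!r}")


class DeltaSet(NamedTuple):
    """Per-measurement normalized deviations in flat group/member order."""

    delta: np.ndarray
    plot_mask: np.ndarray  # True for members of groups with n >= 2
    group_id: np.ndarray


def normalized_deviations(
    groups: Sequence[ReflectionGroup],
    esus: Sequence[float] | None = None,
    mode: str = "inclusive_mean",
) -> DeltaSet:
    """Normalized deviations for every measurement.

    Singletons receive delta = 0 (the inclusive mean equals the measurement)
    and are masked out of normal-plot construction.  ``esus`` optionally
    overrides the stored member sigmas (flat order).
    """
    deltas, mask, gids = [], [], []
    pos = 0
    for gid, g in enumerate(groups):
        sig = (
            np.asarray(esus[pos : pos + g.n], dtype=float)
            if esus is not None
            else g.sigmas
        )
        pos += g.n
        if (sig <= 0).any():
            raise ValueError(f"non-positive e.s.u. in group {g.canonical_hkl}")
        for l, m in enumerate(g.members):
            if g.n == 1:
                deltas.append(0.0)
                mask.append(False)
            else:
                ref = reference_intensity(g, l, mode, esus=sig)
                deltas.append((m.intensity - ref) / sig[l])
                mask.append(True)
            gids.append(gid)
    return DeltaSet(np.array(deltas), np.array(mask), np.array(gids))


def theoretical_quantiles(n: int, rule: str = "centered") -> np.ndarray:
    """Standard-normal theoretical quantiles for a sorted sample of size n."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(1, n + 1)
    if rule == "centered":
        p = (i - 0.5) / n
    elif rule == "expected":
        p = i / (n + 1)
    else:
        raise ValueError(f"unknown plotting-position rule {rule!r}")
    return stats.norm.ppf(p)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class _FlatData(NamedTuple):
    intensity: np.ndarray
    sigma0: np.ndarray
    dev_ref: np.ndarray   # reference for the delta numerator
    sig_ref: np.ndarray   # reference intensity entering the sigma' correction
    seg: np.ndarray       # contiguous segment id per point (for weighted mode)
    flat_index: np.ndarray  # position in the global flat measurement order
    n_excluded_lo: int    # excluded outliers below / above the bulk: the
    n_excluded_hi: int    # survivors keep their interior ranks in the plot


def _flatten(
    groups: Sequence[ReflectionGroup],
    model: int,
    mode: str,
    exclude: np.ndarray | None,
) -> _FlatData:
    """Collect fit arrays from non-excluded members of groups that keep n >= 2."""
    I, s0, dref, sref, seg, fidx = [], [], [], [], [], []
    n_lo = n_hi = 0
    pos = 0
    nseg = 0
    for g in groups:
        n = g.n
        keep = np.ones(n, dtype=bool)
        if exclude is not None:
            keep = ~np.asarray(exclude[pos : pos + n], dtype=bool)
            if n >= 2 and not keep.all():
                # excluded outliers retain their (extreme) plot ranks; split
                # by which side of the group reference they fell on
                out_i = g.intensities[~keep]
                ref = float(g.intensities.mean())
                n_lo += int(np.sum(out_i < ref))
                n_hi += int(np.sum(out_i >= ref))
        if keep.sum() >= 2:
            ints = g.intensities[keep]
            sigs = g.sigmas[keep]
            r = float(ints.max()) if model == 3 else float(ints.mean())
            if mode == "inclusive_mean":
                refs = np.full(ints.size, ints.mean())
            elif mode == "exclusive_mean":
                tot = ints.sum()
                refs = (tot - ints) / (ints.size - 1)
            elif mode == "weighted_mean":
                refs = np.full(ints.size, np.nan)  # recomputed per evaluation
            else:
                raise ValueError(f"unsupported fit reference mode {mode!r}")
            I.append(ints)
            s0.append(sigs)
            dref.append(refs)
            sref.append(np.full(ints.size, r))
            seg.append(np.full(ints.size, nseg))
            fidx.append(pos + np.flatnonzero(keep))
            nseg += 1
        pos += n
    if not I:
        raise ValueError("calibration requires at least one group with n >= 2")
    return _FlatData(
        np.concatenate(I),
        np.concatenate(s0),
        np.concatenate(dref),
        np.concatenate(sref),
        np.concatenate(seg),
        np.concatenate(fidx),
        n_lo,
        n_hi,
    )


def _make_delta_fn(data: _FlatData, mode: str):
    """delta(params) over the flattened fit set."""
    if mode == "weighted_mean":
        nseg = int(data.seg.max()) + 1

        def delta(p: ErrorModelParams) -> np.ndarray:
            sig = corrected_sigma(data.sigma0, data.sig_ref, p)
            w = 1.0 / sig**2
            num = np.bincount(data.seg, weights=w * data.intensity, minlength=nseg)
            den = np.bincount(data.seg, weights=w, minlength=nseg)
            ref = (num / den)[data.seg]
            return (data.intensity - ref) / sig

    else:

        def delta(p: ErrorModelParams) -> np.ndarray:
            sig = corrected_sigma(data.sigma0, data.sig_ref, p)
            return (data.intensity - ref_) / sig

        ref_ = data.dev_ref
    return delta


def _params_from_u(u: np.ndarray, b_scale: float, a_scale: float) -> ErrorModelParams:
    return ErrorModelParams(
        s_fac=float(np.exp(np.clip(u[0], -12, 12))),
        s_b=float(u[1] ** 2 * b_scale),
        s_add=float(u[2] ** 2 * a_scale),
    )


def fit_error_model(
    groups: Sequence[ReflectionGroup],
    model: int = 2,
    cfg: CalibrationConfig | None = None,
    exclude: np.ndarray | None = None,
) -> CalibrationResult:
    """Fit (s_fac, s_B, s_add) by linearizing the normal probability plot.

    ``model`` selects the sigma' reference (2 = group mean, 3 = group max);
    ``exclude`` is an optional per-measurement boolean mask (flat order) of
    outliers left out of the fit.  The minimization runs Nelder-Mead
    supercycles on (log s_fac, sqrt-scaled s_B, sqrt-scaled s_add) with the
    delta ordering frozen inside each cycle and re-sorted between cycles.
    """
    if model not in (2, 3):
        raise ValueError("fit_error_model supports models 2 and 3")
    cfg = cfg or CalibrationConfig()
    data = _flatten(groups, model, cfg.reference_mode, exclude)
    delta_fn = _make_delta_fn(data, cfg.reference_mode)
    n = data.intensity.size
    # Rejected measurements sit beyond the fences.  The clean normal
    # population loses at most the fence-tail fraction per side (fences at
    # +-(0.6745 + 1.349k) sigma); flags beyond that are contamination and
    # carry no rank.  Survivors therefore keep interior ranks for up to that
    # many censored extremes, which prevents both the truncation "stretch"
    # (clean data) and an artificial squeeze (gross contamination).
    p_side = float(stats.norm.cdf(-(0.6745 + 1.349 * cfg.tukey_k)))
    allow = int(round(n * p_side / max(1.0 - 2 * p_side, 1e-9)))
    n_lo = min(data.n_excluded_lo, allow)
    n_hi = min(data.n_excluded_hi, allow)
    n_tot = n + n_lo + n_hi
    i = np.arange(n_lo + 1, n_lo + n + 1)
    if cfg.plotting_position == "centered":
        q = stats.norm.ppf((i - 0.5) / n_tot)
    elif cfg.plotting_position == "expected":
        q = stats.norm.ppf(i / (n_tot + 1))
    else:
        raise ValueError(f"unknown plotting-position rule {cfg.plotting_position!r}")

    # dimensionless parametrization so the simplex sees comparable scales
    ref_scale = max(float(np.median(np.maximum(data.sig_ref, 0.0))), 1e-12)
    sig_scale = max(float(np.median(data.sigma0)), 1e-12)
    b_scale = max(sig_scale**2 / ref_scale, 1e-12)
    a_scale = max(sig_scale / ref_scale, 1e-12)

    p0 = cfg.init_params
    u = np.array(
        [np.log(p0.s_fac), np.sqrt(max(p0.s_b, 0.0) / b_scale), np.sqrt(max(p0.s_add, 0.0) / a_scale)]
    )

    # Each evaluation re-sorts the deltas against the fixed quantiles — the
    # numerically stable limit of the resort-and-refit supercycle (freezing
    # the permutation during a cycle attenuates the fitted scale toward the
    # delta/quantile correlation and relaxes only geometrically).
    def objective(uu: np.ndarray) -> float:
        try:
            d = delta_fn(_params_from_u(uu, b_scale, a_scale))
        except (ValueError, FloatingPointError):
            return np.inf
        return float(np.sum((np.sort(d) - q) ** 2))

    order = np.argsort(delta_fn(_params_from_u(u, b_scale, a_scale)), kind="stable")
    d_prev = np.inf
    converged = False
    n_cycles = 0
    step = 0.35
    for n_cycles in range(1, cfg.max_supercycles + 1):
        u_prev = u.copy()
        simplex = np.vstack([u] + [u + step * e for e in np.eye(3)])
        res = optimize.minimize(
            objective,
            u,
            method="Nelder-Mead",
            options={"initial_simplex": simplex, "xatol": 1e-9, "fatol": 1e-12, "maxiter": 6000},
        )
        u = res.x
        step = max(step * 0.25, 1e-3)  # restarts probe a shrinking neighbourhood
        d_now = delta_fn(_params_from_u(u, b_scale, a_scale))
        new_order = np.argsort(d_now, kind="stable")
        d_val = float(np.sum((np.sort(d_now) - q) ** 2))
        params_stable = np.max(np.abs(u - u_prev)) <= cfg.param_tol
        if (
            np.array_equal(new_order, order)
            or abs(d_prev - d_val) <= cfg.tol * max(1.0, d_val)
            or params_stable
        ):
            order = new_order
            converged = True
            break
        order = new_order
        d_prev = d_val

    params = _params_from_u(u, b_scale, a_scale)
    deltas_sorted = np.sort(delta_fn(params))
    d_final = float(np.sum((deltas_sorted - q) ** 2))
    slope, intercept = np.polyfit(q, deltas_sorted, 1)

    flags = np.zeros(sum(g.n for g in groups), dtype=bool)
    if exclude is not None:
        flags = np.asarray(exclude, dtype=bool).copy()
    return CalibrationResult(
        params=params,
        deltas_sorted=deltas_sorted,
        quantiles=q,
        D=d_final,
        slope=float(slope),
        intercept=float(intercept),
        outlier_flags=flags,
        n_supercycles=n_cycles,
        n_outlier_iters=0,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Outlier rejection
# ---------------------------------------------------------------------------

def tukey_outliers(
    deltas: Sequence[float],
    k: float = 1.5,
    group_ids: Sequence[int] | None = None,
) -> np.ndarray:
    """Tukey-fence outlier flags: delta outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles by linear interpolation on the sorted values.  When
    ``group_ids`` is given, the paired-reflection rule applies: in a group of
    exactly two measurements, flagging one flags the other.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size < 4:
        warnings.warn("fewer than 4 deltas: no outlier flags assigned", stacklevel=2)
        return np.zeros(deltas.size, dtype=bool)
    q1, q3 = np.percentile(deltas, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags = (deltas < lo) | (deltas > hi)
    if group_ids is not None:
        gids = np.asarray(group_ids)
        uniq, counts = np.unique(gids, return_counts=True)
        pairs = set(uniq[counts == 2])
        for gid in np.unique(gids[flags]):
            if gid in pairs:
                flags |= gids == gid
    return flags


def _deltas_all(groups: Sequence[ReflectionGroup], params: ErrorModelParams | None,
                model: int, mode: str) -> DeltaSet:
    """Deltas over all measurements, with e.s.u.'s corrected by ``params`` (or raw)."""
    if params is None:
        return normalized_deviations(groups, mode=mode)
    esus = []
    for g in groups:
        ref = g.max_intensity if model == 3 else g.mean_intensity
        esus.append(corrected_sigma(g.sigmas, np.full(g.n, ref), params))
    return normalized_deviations(groups, esus=np.concatenate(esus), mode=mode)


def calibrate(
    groups: Sequence[ReflectionGroup],
    model: int = 3,
    cfg: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Alternate error-model fitting and Tukey outlier rejection to convergence.

    The first rejection pass runs on the uncorrected data; each subsequent
    pass corrects the e.s.u.'s of *all* measurements (outliers included) with
    the parameters fitted on the non-outliers and re-applies the fences.
    Convergence: relative parameter change below ``cfg.param_tol`` and a
    stable outlier count.
    """
    cfg = cfg or CalibrationConfig()

    ds0 = _deltas_all(groups, None, model, cfg.reference_mode)
    flags = np.zeros(ds0.delta.size, dtype=bool)
    plot = ds0.plot_mask
    sub = tukey_outliers(ds0.delta[plot], cfg.tukey_k, ds0.group_id[plot])
    flags[np.flatnonzero(plot)] = sub

    result: CalibrationResult | None = None
    prev_params: np.ndarray | None = None
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_outlier_iters + 1):
        result = fit_error_model(groups, model, cfg, exclude=flags)
        p = np.array(result.params.as_tuple())

        ds = _deltas_all(groups, result.params, model, cfg.reference_mode)
        new_flags = np.zeros_like(flags)
        sub = tukey_outliers(ds.delta[plot], cfg.tukey_k, ds.group_id[plot])
        new_flags[np.flatnonzero(plot)] = sub

        if prev_params is not None:
            dp = np.abs(p - prev_params) / np.maximum(np.abs(prev_params), 1e-12)
            if dp.max() < cfg.param_tol and new_flags.sum() == flags.sum():
                flags = new_flags
                converged = True
                break
        prev_params = p
        flags = new_flags
    else:
        # oscillating or slowly drifting outlier set: keep the final iterate
        logger.warning("outlier iteration did not converge in %d passes", cfg.max_outlier_iters)

    assert result is not None
    result.outlier_flags = flags
    result.n_outlier_iters = n_iter
    result.converged = converged and result.converged
    return result
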