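"""Synthetic unmerged reflection datasets with known ground truth.

The generator emulates the statistical structure the calibration assumes:
true intensities follow acentric Wilson (exponential) statistics, each unique
reflection is observed with a configurable multiplicity (defaults emulate the
low-redundancy regime of real electron-diffraction datasets, with substantial
mass at n = 1 and n = 2), measurement errors are Gaussian with a true standard
deviation following the three-parameter model for known (s_fac, s_B, s_add),
and a configurable fraction of measurements carries grossly inflated errors.
The stored sigma of each measurement is the *uncorrected* counting-statistics
value, so recovering the true parameters is a well-posed calibration exercise.

``consistency`` controls what the true deviations are referenced to:

* ``"true"`` — measurement = truth + N(0, sigma'(truth)); deviations from the
  realized group mean then carry the inclusive-mean factor (n-1)/n;
* ``"mean"`` — within-group error draws are centered and rescaled so the
  deviation of each member from the realized group mean is exactly
  N(0, sigma'(truth)) marginally (the realized mean equals the truth);
* ``"max"`` — like "mean", but the error scale solves the fixed point
  s = sigma'(max of the realized members), matching a model-3 calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .error_models import ErrorModelParams, corrected_sigma
from .reflection_data import Measurement, ReflectionGroup, UnitCell

__all__ = [
    "CountingSigmaModel",
    "SyntheticSpec",
    "GroundTruth",
    "simulate_dataset",
    "simulate_groups",
    "recovery_report",
]

# low-redundancy multiplicity profile: ~30% singletons, ~25% pairs
DEFAULT_MULTIPLICITY = {1: 0.30, 2: 0.25, 3: 0.15, 4: 0.12, 5: 0.08, 6: 0.06, 8: 0.04}


@dataclass(frozen=True)
class CountingSigmaModel:
    """Counting-statistics e.s.u. rule: sigma0(I) = sqrt(gain*max(I,0) + b^2).

    The background term b (counts) models the rim-subtraction contribution
    that keeps weak reflections from having vanishing uncertainties.  Real
    frames differ in exposure and background level, so b is drawn per unique
    reflection, uniformly over ``floor * (1 +- floor_spread)``.  This
    intensity-independent variation is what makes the scale parameter s_fac
    statistically separable from the intensity-proportional s_B term.
    """

    gain: float = 1.0
    floor: float = 45.0
    floor_spread: float = 0.6

    def sample_floor(self, rng: np.random.Generator) -> float:
        lo = self.floor * (1.0 - self.floor_spread)
        hi = self.floor * (1.0 + self.floor_spread)
        return float(rng.uniform(lo, hi))

    def __call__(self, intensity, floor: float | None = None):
        b = self.floor if floor is None else floor
        return np.sqrt(self.gain * np.maximum(np.asarray(intensity, dtype=float), 0.0)
                       + b**2)


@dataclass
class SyntheticSpec:
    """Study conditions for one simulated dataset."""

    n_groups: int = 5000
    multiplicity_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLICITY)
    )
    wilson_scale: float = 400.0
    cell: UnitCell = field(default_factory=lambda: UnitCell(15.0, 15.0, 15.0))
    d_star_range: tuple[float, float] = (0.05, 1.0)
    true_params: ErrorModelParams = field(
        default_factory=lambda: ErrorModelParams(1.1, 1.0, 0.05)
    )
    base_sigma: CountingSigmaModel = field(default_factory=CountingSigmaModel)
    outlier_fraction: float = 0.0
    outlier_inflation: float = 20.0
    consistency: str = "true"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.multiplicity_dist.values())
        if not np.isclose(total, 1.0):
            raise ValueError("multiplicity probabilities must sum to 1")
        if any(n < 1 for n in self.multiplicity_dist):
            raise ValueError("multiplicities must be >= 1")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.consistency not in ("true", "mean", "max"):
            raise ValueError("consistency must be 'true', 'mean' or 'max'")


@dataclass
class GroundTruth:
    """Per-group and per-measurement truth for a simulated dataset."""

    true_intensity: np.ndarray      # per group
    multiplicity: np.ndarray        # per group
    group_index: np.ndarray         # per measurement
    true_sigma: np.ndarray          # per measurement: the corrected (true) error scale
    true_delta: np.ndarray          # per measurement: error draw / true_sigma
    outlier: np.ndarray             # per measurement
    params: ErrorModelParams
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "params": {"s_fac": self.params.s_fac, "s_b": self.params.s_b,
                       "s_add": self.params.s_add},
            "seed": int(self.seed),
            "n_groups": int(self.true_intensity.size),
            "n_measurements": int(self.group_index.size),
            "n_outliers": int(self.outlier.sum()),
            "true_intensity": self.true_intensity.tolist(),
            "multiplicity": self.multiplicity.tolist(),
            "group_index": self.group_index.tolist(),
            "outlier": self.outlier.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _distinct_hkls(n: int) -> np.ndarray:
    """Distinct all-positive index triples (orbit-distinct under sign-change groups)."""
    g = np.arange(n)
    return np.stack([g % 30 + 1, (g // 30) % 30 + 1, g // 900 + 1], axis=1)


def simulate_dataset(spec: SyntheticSpec) -> tuple[list[Measurement], GroundTruth]:
    """Draw one unmerged dataset; byte-identical output for a fixed seed.

    Members of a group share an index triple but carry random equivalent sign
    combinations (Laue class mmm regroups them); resolutions are drawn
    uniformly over ``d_star_range`` and attached to the measurements.
    """
    rng = np.random.default_rng(spec.seed)
    ng = spec.n_groups
    mult_vals = np.array(sorted(spec.multiplicity_dist))
    mult_probs = np.array([spec.multiplicity_dist[int(v)] for v in mult_vals])

    true_i = rng.exponential(spec.wilson_scale, size=ng)
    mult = rng.choice(mult_vals, size=ng, p=mult_probs)
    dstar = rng.uniform(*spec.d_star_range, size=ng)
    hkls = _distinct_hkls(ng)

    measurements: list[Measurement] = []
    group_index, true_sigma, true_delta, outlier = [], [], [], []
    p = spec.true_params
    for gi in range(ng):
        n = int(mult[gi])
        mu = true_i[gi]
        if hasattr(spec.base_sigma, "sample_floor"):
            sigma0 = float(spec.base_sigma(mu, spec.base_sigma.sample_floor(rng)))
        else:
            sigma0 = float(spec.base_sigma(mu))
        z = rng.standard_normal(n)
        is_out = rng.random(n) < spec.outlier_fraction

        if spec.consistency == "true" or n == 1:
            scale = float(corrected_sigma(sigma0, mu, p))
            dev = z.copy()
        elif spec.consistency == "mean":
            scale = float(corrected_sigma(sigma0, mu, p))
            dev = (z - z.mean()) * np.sqrt(n / (n - 1))
        else:  # "max": error scale consistent with the realized group maximum
            dev = (z - z.mean()) * np.sqrt(n / (n - 1))
            scale = float(corrected_sigma(sigma0, mu, p))
            for _ in range(8):
                m_real = mu + scale * dev.max()
                new = float(corrected_sigma(sigma0, max(m_real, mu), p))
                if abs(new - scale) < 1e-10 * max(scale, 1.0):
                    scale = new
                    break
                scale = new

        err = scale * dev
        err[is_out] *= spec.outlier_inflation
        values = mu + err
        signs = rng.choice([-1, 1], size=(n, 3))
        for l in range(n):
            h, k, lidx = (int(s * v) for s, v in zip(signs[l], hkls[gi]))
            measurements.append(
                Measurement((h, k, lidx), float(values[l]), sigma0, frame=l,
                            d_star=float(dstar[gi]))
            )
        group_index.extend([gi] * n)
        true_sigma.extend([scale] * n)
        true_delta.extend((dev * np.where(is_out, spec.outlier_inflation, 1.0)).tolist())
        outlier.extend(is_out.tolist())

    truth = GroundTruth(
        true_intensity=true_i,
        multiplicity=mult.astype(int),
        group_index=np.array(group_index),
        true_sigma=np.array(true_sigma),
        true_delta=np.array(true_delta),
        outlier=np.array(outlier, dtype=bool),
        params=p,
        seed=spec.seed,
    )
    return measurements, truth


def simulate_groups(spec: SyntheticSpec) -> tuple[list[ReflectionGroup], GroundTruth]:
    """Simulate and return ready-made groups (one per unique reflection).

    Equivalent to grouping the measurement list under Laue class mmm, but
    built directly from the generator's own group structure.
    """
    measurements, truth = simulate_dataset(spec)
    groups: list[ReflectionGroup] = []
    pos = 0
    for gi, n in enumerate(truth.multiplicity):
        members = measurements[pos : pos + int(n)]
        canonical = tuple(int(abs(x)) for x in members[0].hkl)
        groups.append(ReflectionGroup(canonical, list(members)))
        pos += int(n)
    return groups, truth


def recovery_report(
    true: ErrorModelParams,
    fitted: ErrorModelParams,
    rel_tol: float = 0.1,
) -> dict[str, dict[str, float | bool]]:
    """Per-parameter absolute and relative errors between truth and fit."""
    report: dict[str, dict[str, float | bool]] = {}
    for name, t, f in [
        ("s_fac", true.s_fac, fitted.s_fac),
        ("s_b", true.s_b, fitted.s_b),
        ("s_add", true.s_add, fitted.s_add),
    ]:
        abs_err = abs(f - t)
        rel_err = abs_err / abs(t) if t != 0 else float("inf") if abs_err else 0.0
        report[name] = {
            "true": t,
            "fitted": f,
            "abs_error": abs_err,
            "rel_error": rel_err,
            "exceeds_tol": rel_err > rel_tol,
        }
    return report
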