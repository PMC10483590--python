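"""Reflection lists, hkl file I/O, resolution and symmetry-equivalence grouping.

The central object downstream is the :class:`ReflectionGroup`: all measurements
of one unique reflection under the chosen Laue class (optionally completed by
Friedel inversion).  Error-model calibration compares the scatter of the
members of each group against the estimated standard uncertainties (e.s.u.'s)
of the individual measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "UnitCell",
    "Measurement",
    "ReflectionGroup",
    "SymmetrySetting",
    "LAUE_CLASSES",
    "read_hkl",
    "write_hkl",
    "d_star",
    "group_equivalents",
]


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        # positive-definiteness of the metric is checked via its eigenvalues
        g = self.metric()
        if np.linalg.eigvalsh(g).min() <= 0:
            raise ValueError("degenerate unit cell: metric tensor not positive definite")

    def metric(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, Angstrom^2)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1 (Angstrom^-2)."""
        return np.linalg.inv(self.metric())


@dataclass
class Measurement:
    """One observation of a reflection.

    ``intensity`` is the background-corrected integrated intensity in detector
    counts (may be negative after background subtraction); ``sigma`` its
    counting-statistics e.s.u. (same units).  ``frame`` optionally identifies
    the source diffraction pattern, ``d_star`` the resolution in 1/Angstrom.
    """

    hkl: tuple[int, int, int]
    intensity: float
    sigma: float
    frame: int | None = None
    d_star: float | None = None


@dataclass
class ReflectionGroup:
    """All symmetry-equivalent measurements of one unique reflection."""

    canonical_hkl: tuple[int, int, int]
    members: list[Measurement]

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([m.intensity for m in self.members])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([m.sigma for m in self.members])

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))

    @property
    def max_intensity(self) -> float:
        return float(np.max(self.intensities))

    @property
    def sample_std(self) -> float | None:
        """Bessel-corrected standard deviation of member intensities; None for n=1."""
        if self.n < 2:
            return None
        return float(np.std(self.intensities, ddof=1))

    @property
    def d_star(self) -> float | None:
        """Group resolution: mean of member d* values when available."""
        ds = [m.d_star for m in self.members if m.d_star is not None]
        if not ds:
            return None
        return float(np.mean(ds))

    def copy(self) -> "ReflectionGroup":
        return ReflectionGroup(self.canonical_hkl, [replace(m) for m in self.members])


# ---------------------------------------------------------------------------
# Laue-class operator tables
# ---------------------------------------------------------------------------

def _close_group(mats: Iterable[np.ndarray]) -> list[np.ndarray]:
    """Close a set of integer 3x3 matrices under multiplication (incl. identity)."""
    seen: dict[bytes, np.ndarray] = {}
    eye = np.eye(3, dtype=int)
    frontier = [eye] + [np.asarray(m, dtype=int) for m in mats]
    for m in frontier:
        seen[m.tobytes()] = m
    while frontier:
        new: list[np.ndarray] = []
        for m in frontier:
            for g in list(seen.values()):
                for prod in (m @ g, g @ m):
                    key = prod.tobytes()
                    if key not in seen:
                        if len(seen) > 48:
                            raise ValueError("operator set does not close (order > 48)")
                        seen[key] = prod
                        new.append(prod)
        frontier = new
    return list(seen.values())


def _diag(x: int, y: int, z: int) -> list[list[int]]:
    return [[x, 0, 0], [0, y, 0], [0, 0, z]]


_R4Z = [[0, -1, 0], [1, 0, 0], [0, 0, 1]]
_R3Z = [[0, -1, 0], [1, -1, 0], [0, 0, 1]]   # hexagonal threefold
_R6Z = [[1, -1, 0], [1, 0, 0], [0, 0, 1]]    # hexagonal sixfold
_R2HEX = [[0, 1, 0], [1, 0, 0], [0, 0, -1]]  # twofold in the hexagonal basal plane
_R3CUB = [[0, 0, 1], [1, 0, 0], [0, 1, 0]]   # cubic body-diagonal threefold

# Rotational subgroups of the 11 Laue classes; Friedel inversion is applied
# separately via SymmetrySetting.add_friedel (the Laue group proper is the
# rotation group times {1, -1}).
_LAUE_GENERATORS: dict[str, list[list[list[int]]]] = {
    "-1": [],
    "2/m": [_diag(-1, 1, -1)],                 # unique axis b
    "mmm": [_diag(-1, -1, 1), _diag(1, -1, -1)],
    "4/m": [_R4Z],
    "4/mmm": [_R4Z, _diag(1, -1, -1)],
    "-3": [_R3Z],
    "-3m": [_R3Z, _R2HEX],
    "6/m": [_R6Z],
    "6/mmm": [_R6Z, _R2HEX],
    "m-3": [_diag(-1, -1, 1), _diag(1, -1, -1), _R3CUB],
    "m-3m": [_diag(-1, -1, 1), _diag(1, -1, -1), _R3CUB, _R4Z],
}

_LAUE_ALIASES = {
    "m3": "m-3",
    "m3m": "m-3m",
    "-3m1": "-3m",
    "-31m": "-3m",
    "1": "-1",
}

LAUE_CLASSES = tuple(_LAUE_GENERATORS)


def laue_operators(name: str) -> list[np.ndarray]:
    """Rotation operators (without inversion) of a Laue class, closed under composition."""
    key = name.strip().lower().replace("−", "-")
    key = _LAUE_ALIASES.get(key, key)
    if key not in _LAUE_GENERATORS:
        raise ValueError(f"unknown Laue class {name!r}; known: {', '.join(LAUE_CLASSES)}")
    return _close_group(np.asarray(g, dtype=int) for g in _LAUE_GENERATORS[key])


@dataclass
class SymmetrySetting:
    """Laue symmetry used for grouping equivalents.

    Either a Laue-class name or an explicit list of 3x3 integer matrices acting
    on hkl.  ``add_friedel`` appends the inversion -1, merging Friedel pairs
    (a centre of symmetry imposed in the averaging).
    """

    laue_class: str | None = None
    operators: Sequence[np.ndarray] | None = None
    add_friedel: bool = True

    def matrices(self) -> np.ndarray:
        """Full closed operator set as an (n_ops, 3, 3) integer array."""
        if self.operators is not None:
            ops = _close_group(np.asarray(m, dtype=int) for m in self.operators)
        elif self.laue_class is not None:
            ops = laue_operators(self.laue_class)
        else:
            raise ValueError("SymmetrySetting requires a laue_class or explicit operators")
        if not ops:
            raise ValueError("empty operator set")
        if self.add_friedel:
            ops = _close_group(list(ops) + [-np.eye(3, dtype=int)])
        return np.stack(ops)


# ---------------------------------------------------------------------------
# hkl file I/O
# ---------------------------------------------------------------------------

_FIXED_SLICES = [(0, 4), (4, 8), (8, 12), (12, 20), (20, 28), (28, 32)]


def read_hkl(path: str | Path, dialect: str = "shelx_fixed") -> list[Measurement]:
    """Read an unmerged reflection list.

    ``shelx_fixed`` expects the HKLF-style 3I4,2F8.2 layout (optional I4 batch
    number); ``free`` expects whitespace-separated ``h k l I sigma`` with any
    trailing columns ignored.  An all-zero index record terminates the file
    (SHELX convention).  Records with sigma <= 0 are dropped and reported via
    logging.
    """
    path = Path(path)
    records: list[Measurement] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            try:
                if dialect == "shelx_fixed":
                    h = int(line[0:4])
                    k = int(line[4:8])
                    l = int(line[8:12])
                    intensity = float(line[12:20])
                    sigma = float(line[20:28])
                    frame_field = line[28:32].strip()
                    frame = int(frame_field) if frame_field else None
                elif dialect == "free":
                    parts = line.split()
                    if len(parts) < 5:
                        raise ValueError("expected at least 5 columns")
                    h, k, l = (int(p) for p in parts[:3])
                    intensity, sigma = float(parts[3]), float(parts[4])
                    frame = None
                else:
                    raise ValueError(f"unknown hkl dialect {dialect!r}")
            except ValueError as exc:
                raise ValueError(f"{path}: malformed hkl record at line {lineno}: {exc}") from exc
            if (h, k, l) == (0, 0, 0):
                break  # terminator record
            if sigma <= 0:
                n_rejected += 1
                continue
            records.append(Measurement((h, k, l), intensity, sigma, frame=frame))
    if n_rejected:
        logger.warning("%s: rejected %d record(s) with sigma <= 0", path, n_rejected)
    if not records:
        raise ValueError(f"{path}: no reflection records found")
    return records


def write_hkl(records: Sequence, path: str | Path, dialect: str = "shelx_fixed") -> None:
    """Write measurements or merged reflections.

    Records need ``hkl``, ``intensity`` and ``sigma`` attributes; a
    multiplicity attribute ``n`` (merged reflections) is written as an extra
    integer column in either dialect.
    """
    if len(records) == 0:
        raise ValueError("refusing to write an empty reflection list")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            h, k, l = rec.hkl
            extra = getattr(rec, "n", None)
            if extra is None:
                extra = getattr(rec, "frame", None)
            if dialect == "shelx_fixed":
                line = f"{h:4d}{k:4d}{l:4d}{rec.intensity:8.2f}{rec.sigma:8.2f}"
                if extra is not None:
                    line += f"{extra:4d}"
            elif dialect == "free":
                line = f"{h} {k} {l} {rec.intensity:.6g} {rec.sigma:.6g}"
                if extra is not None:
                    line += f" {extra}"
            else:
                raise ValueError(f"unknown hkl dialect {dialect!r}")
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Resolution and grouping
# ---------------------------------------------------------------------------

def d_star(cell: UnitCell, hkl: Sequence[int]) -> float:
    """Reciprocal-space vector length d* = 1/d = sqrt(h^T G* h) in 1/Angstrom."""
    h = np.asarray(hkl, dtype=float)
    return float(math.sqrt(h @ cell.reciprocal_metric() @ h))


def canonical_index(hkl: Sequence[int], ops: np.ndarray) -> tuple[int, int, int]:
    """Lexicographically greatest member of the symmetry orbit of hkl."""
    h = np.asarray(hkl, dtype=int)
    orbit = ops @ h
    best = max(map(tuple, orbit))
    return (int(best[0]), int(best[1]), int(best[2]))


def group_equivalents(
    measurements: Sequence[Measurement], sym: SymmetrySetting
) -> list[ReflectionGroup]:
    """Partition measurements into symmetry-equivalence groups.

    Two measurements land in the same group iff their indices are related by
    an operator of the setting (including Friedel inversion when enabled).
    The canonical index is the lexicographically greatest orbit member; groups
    are returned sorted by canonical index so the partition is independent of
    input order.
    """
    if not measurements:
        raise ValueError("no measurements to group")
    ops = sym.matrices()

    hkls = np.array([m.hkl for m in measurements], dtype=int)  # (N, 3)
    # apply every operator, keep the running lexicographic maximum
    best = hkls.copy()
    for op in ops:
        cand = hkls @ op.T
        gt = (cand[:, 0] > best[:, 0]) | (
            (cand[:, 0] == best[:, 0])
            & ((cand[:, 1] > best[:, 1]) | ((cand[:, 1] == best[:, 1]) & (cand[:, 2] > best[:, 2])))
        )
        best[gt] = cand[gt]

    buckets: dict[tuple[int, int, int], list[Measurement]] = {}
    for m, row in zip(measurements, best):
        key = (int(row[0]), int(row[1]), int(row[2]))
        buckets.setdefault(key, []).append(m)
    return [ReflectionGroup(key, members) for key, members in sorted(buckets.items())]
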