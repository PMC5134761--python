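"""Geometry of the conformational search space.

The search space is a hyper-rectangle over the independent torsion angles
theta_i, each dimension bounded by [theta_L_i, theta_U_i] in degrees.  A
dimension may be *periodic*, meaning it covers the full 360 deg circle;
distances and midpoints on periodic dimensions use the shorter arc.  Each
dimension carries a half-spacing ``half_spacing`` (the +/- half-width of the
hyper-rectangular cell a grid-based local model is intended to cover), which
also sets the regular-grid pitch: grid cells are ``2 * half_spacing`` wide.

All angles are degrees throughout the package; energies are kJ/mol.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: absolute tolerance (degrees) used for span/divisibility/antipodal checks
ANGLE_TOL = 1e-9


class DomainError(ValueError):
    """Invalid search-domain specification."""


class DimensionMismatchError(ValueError):
    """A torsion vector's length does not match the domain dimension."""


class AntipodalPairError(ValueError):
    """Two angles on a periodic dimension are exactly 180 deg apart.

    The midpoint along the circle is then ambiguous; callers are expected to
    skip such pairs (they are always bracketed by nearer models in practice).
    """


@dataclass(frozen=True)
class TorsionDomain:
    """Per-torsion bounds, periodicity and grid half-spacing.

    Parameters
    ----------
    lower, upper:
        Bounds in degrees, per dimension.  For periodic dimensions the span
        ``upper - lower`` must be exactly 360.
    periodic:
        Whether each dimension wraps around the full circle.
    half_spacing:
        Per-dimension half-width (degrees) of a regular-grid cell; the grid
        pitch is twice this value.
    names:
        Optional torsion labels (e.g. ``T1`` .. ``T7``).
    """

    lower: np.ndarray
    upper: np.ndarray
    periodic: np.ndarray
    half_spacing: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for attr in ("lower", "upper", "half_spacing"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        object.__setattr__(self, "periodic", np.asarray(self.periodic, dtype=bool))
        n = self.lower.size
        if not (self.upper.size == n and self.periodic.size == n and self.half_spacing.size == n):
            raise DomainError("lower/upper/periodic/half_spacing must have equal length")
        if not self.names:
            object.__setattr__(self, "names", tuple(f"T{i + 1}" for i in range(n)))
        if len(self.names) != n:
            raise DomainError(f"expected {n} names, got {len(self.names)}")
        for i in range(n):
            span = self.upper[i] - self.lower[i]
            if self.periodic[i]:
                if abs(span - 360.0) > ANGLE_TOL:
                    raise DomainError(
                        f"dimension {i} ({self.names[i]}): periodic span must be 360, got {span}"
                    )
            elif span <= 0:
                raise DomainError(
                    f"dimension {i} ({self.names[i]}): lower bound must be below upper, "
                    f"got [{self.lower[i]}, {self.upper[i]}]"
                )
            if self.half_spacing[i] <= 0:
                raise DomainError(f"dimension {i} ({self.names[i]}): half_spacing must be > 0")

    @property
    def n(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, v: np.ndarray, atol: float = ANGLE_TOL) -> bool:
        v = self.check_vector(v)
        lo_ok = v >= self.lower - atol
        hi = np.where(self.periodic, v < self.upper, v <= self.upper + atol)
        return bool(np.all(lo_ok) and np.all(hi))

    def check_vector(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.n,):
            bad = v.ndim if v.ndim != 1 else v.size
            raise DimensionMismatchError(
                f"torsion vector has length {bad}, domain has {self.n} dimensions"
            )
        return v

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "torsions": [
                {
                    "name": self.names[i],
                    "lower": float(self.lower[i]),
                    "upper": float(self.upper[i]),
                    "periodic": bool(self.periodic[i]),
                    "half_spacing": float(self.half_spacing[i]),
                }
                for i in range(self.n)
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TorsionDomain":
        if not isinstance(data, dict) or "torsions" not in data:
            raise DomainError("domain config must be a mapping with a 'torsions' list")
        entries = data["torsions"]
        if not isinstance(entries, list) or not entries:
            raise DomainError("'torsions' must be a non-empty list")
        req = {"lower", "upper", "half_spacing"}
        lower, upper, periodic, spacing, names = [], [], [], [], []
        for i, e in enumerate(entries):
            if not isinstance(e, dict):
                raise DomainError(f"torsions[{i}]: expected a mapping")
            missing = req - e.keys()
            if missing:
                raise DomainError(f"torsions[{i}]: missing fields {sorted(missing)}")
            for key in ("lower", "upper", "half_spacing"):
                if not isinstance(e[key], (int, float)) or isinstance(e[key], bool):
                    raise DomainError(f"torsions[{i}].{key}: expected a number, got {e[key]!r}")
            lower.append(float(e["lower"]))
            upper.append(float(e["upper"]))
            periodic.append(bool(e.get("periodic", False)))
            spacing.append(float(e["half_spacing"]))
            names.append(str(e.get("name", f"T{i + 1}")))
        return cls(np.array(lower), np.array(upper), np.array(periodic), np.array(spacing), tuple(names))

    @classmethod
    def from_file(cls, path) -> "TorsionDomain":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)


def canonicalize(v: np.ndarray, d: TorsionDomain) -> np.ndarray:
    """Wrap periodic coordinates into [lower, upper); leave others unchanged."""
    v = d.check_vector(v).copy()
    per = d.periodic
    v[per] = d.lower[per] + np.mod(v[per] - d.lower[per], 360.0)
    # mod can return exactly 360 - eps rounding to the upper bound
    v[per & (v >= d.upper)] -= 360.0
    return v


def signed_delta(a: np.ndarray, b: np.ndarray, d: TorsionDomain) -> np.ndarray:
    """Per-dimension signed difference a - b, shorter-arc on periodic dims.

    Periodic components lie in (-180, 180]; non-periodic components are the
    plain difference.
    """
    a = d.check_vector(a)
    b = d.check_vector(b)
    delta = a - b
    per = d.periodic
    delta[per] = np.mod(delta[per] + 180.0, 360.0) - 180.0
    return delta


def distance(a: np.ndarray, b: np.ndarray, d: TorsionDomain) -> float:
    """Euclidean distance in degrees, shorter-arc per periodic dimension."""
    return float(np.linalg.norm(signed_delta(a, b, d)))


def midpoint(a: np.ndarray, b: np.ndarray, d: TorsionDomain) -> np.ndarray:
    """Midpoint along the shorter arc (periodic) / arithmetic mean (bounded).

    Raises
    ------
    AntipodalPairError
        If a periodic component differs by exactly 180 deg, where the
        shorter-arc midpoint is ambiguous.
    """
    delta = signed_delta(a, b, d)
    if np.any(np.abs(np.abs(delta[d.periodic]) - 180.0) <= ANGLE_TOL):
        raise AntipodalPairError(
            "antipodal periodic pair: shorter-arc midpoint is ambiguous; skip the pair"
        )
    return canonicalize(d.check_vector(b) + 0.5 * delta, d)


def _grid_1d(lo: float, up: float, half: float, periodic: bool, convention: str) -> np.ndarray:
    span = up - lo
    cells = span / (2.0 * half)
    if abs(cells - round(cells)) > 1e-9:
        raise DomainError(
            f"grid spacing 2*{half} does not divide span {span} (cells={cells})"
        )
    cells = int(round(cells))
    if convention == "centered":
        return lo + half + 2.0 * half * np.arange(cells)
    if convention == "nodes":
        count = cells if periodic else cells + 1
        return lo + 2.0 * half * np.arange(count)
    raise ValueError(f"unknown grid convention {convention!r} (use 'centered' or 'nodes')")


def regular_grid(d: TorsionDomain, convention: str = "centered") -> list[np.ndarray]:
    """Cartesian-product regular grid over the domain.

    ``centered`` places points at cell centres (lower + half_spacing, then
    every 2*half_spacing); ``nodes`` places points at cell boundaries
    including both endpoints for bounded dimensions (the wrap-around endpoint
    is merged for periodic ones).  Ordering is lexicographic: the first
    dimension varies slowest.
    """
    axes = [
        _grid_1d(d.lower[i], d.upper[i], d.half_spacing[i], bool(d.periodic[i]), convention)
        for i in range(d.n)
    ]
    return [np.array(pt, dtype=float) for pt in itertools.product(*axes)]
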