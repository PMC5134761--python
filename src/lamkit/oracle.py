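"""Energy oracles for the intramolecular surface.

A synthetic analytic potential stands in for the constrained quantum-chemistry
calculations that produce reference energies in a crystal-structure-prediction
workflow.  The full energy over independent torsions theta (degrees) and
dependent coordinates beta (unitless) is

    E(theta, beta) = sum_t V_t * (1 - cos(k_t * theta_i + phi_t))        (Fourier)
                   + sum_c W_c * cos(k_i theta_i + phi_i) * cos(k_j theta_j + phi_j)
                   + sum_q 1/2 * kq * (theta_i - theta0)^2               (quadratic)
                   + sum_m 1/2 * kappa_m * (beta_m - beta_hat_m(theta))^2

with harmonic dependent coordinates relaxing onto a smooth target

    beta_hat_m(theta) = beta0_m + sum sin-terms + sum linear terms.

Because the dependent part is harmonic about beta_hat, the constrained
minimum over beta at fixed theta is analytic: beta* = beta_hat(theta) and
E_min(theta) is the torsional part alone.  Quadratic terms (used by the
``quadratic`` preset, for which second-order local models are globally exact)
break the 360-degree periodicity that otherwise holds in every theta_i.

The *intramolecular energy penalty* reported to the rest of the package is
Delta_E_intra(theta) = E_min(theta) - U_global, where U_global is the
unconstrained global-minimum energy of the molecule.

External engines can be plugged in by implementing the small
:class:`EnergyOracle` protocol (``constrained_minimize``, ``oracle_id``,
``u_global``); no quantum-chemistry caller ships with the package, and
level-of-theory strings are carried as opaque provenance tags only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.optimize import minimize

from .space import TorsionDomain

DEG = np.pi / 180.0


class SpecError(ValueError):
    """Invalid potential specification."""


# ---------------------------------------------------------------------------
# potential specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FourierTerm:
    """V * (1 - cos(k*theta_i + phase))."""

    dim: int
    k: int
    v: float
    phase: float = 0.0


@dataclass(frozen=True)
class CouplingTerm:
    """W * cos(k_i*theta_i + phase_i) * cos(k_j*theta_j + phase_j)."""

    dims: tuple[int, int]
    w: float
    k: tuple[int, int] = (1, 1)
    phases: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class BumpTerm:
    """Localized feature: amp * prod_i exp(conc_i * (cos(theta_i - center_i) - 1)).

    A periodized Gaussian (von Mises profile) per listed dimension; angular
    half-width is roughly ``1/sqrt(conc)`` radians.  Positive amplitudes model
    localized repulsive features (e.g. steric clashes), negative ones
    attractive pockets (e.g. an intramolecular hydrogen bond).
    """

    dims: tuple[int, ...]
    amp: float
    centers: tuple[float, ...]
    conc: tuple[float, ...]


@dataclass(frozen=True)
class QuadraticTerm:
    """1/2 * curvature * (theta_i - center)^2, curvature in kJ/mol/deg^2."""

    dim: int
    curvature: float
    center: float = 0.0


@dataclass(frozen=True)
class BilinearTerm:
    """w * (theta_i - center_i) * (theta_j - center_j), w in kJ/mol/deg^2.

    Tilts a quadratic basin so its principal axes are not torsion-aligned;
    like :class:`QuadraticTerm` it is exactly captured by a second-order
    local model and breaks periodicity.
    """

    dims: tuple[int, int]
    w: float
    centers: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class SinTarget:
    """amp * sin(k*theta_i + phase) contribution to a dependent target."""

    dim: int
    k: int
    amp: float
    phase: float = 0.0


@dataclass(frozen=True)
class DependentModel:
    """One dependent coordinate: harmonic about a smooth target of theta.

    target(theta) = beta0 + sum sin-terms + sum_i linear[i] * theta_i;
    stiffness kappa is in kJ/mol per (unit of beta)^2.
    """

    beta0: float = 0.0
    sin_terms: tuple[SinTarget, ...] = ()
    linear: tuple[tuple[int, float], ...] = ()
    kappa: float = 1.0


@dataclass(frozen=True)
class PotentialSpec:
    """A synthetic analytic intramolecular energy surface."""

    n_indep: int
    fourier: tuple[FourierTerm, ...] = ()
    coupling: tuple[CouplingTerm, ...] = ()
    quadratic: tuple[QuadraticTerm, ...] = ()
    bilinear: tuple[BilinearTerm, ...] = ()
    bumps: tuple[BumpTerm, ...] = ()
    dependents: tuple[DependentModel, ...] = ()
    seed: int | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_indep < 1:
            raise SpecError("n_indep must be >= 1")
        for t in self.fourier:
            if not (0 <= t.dim < self.n_indep):
                raise SpecError(f"fourier term dimension {t.dim} out of range")
            if t.k < 1:
                raise SpecError("fourier multiplicity k must be >= 1")
        for c in self.coupling:
            i, j = c.dims
            if not (0 <= i < self.n_indep and 0 <= j < self.n_indep and i != j):
                raise SpecError(f"coupling dims {c.dims} invalid")
        for bump in self.bumps:
            if len(bump.dims) != len(bump.centers) or len(bump.dims) != len(bump.conc):
                raise SpecError("bump dims/centers/conc must have equal length")
            for dim in bump.dims:
                if not (0 <= dim < self.n_indep):
                    raise SpecError(f"bump dimension {dim} out of range")
            if any(c <= 0 for c in bump.conc):
                raise SpecError("bump concentrations must be > 0")
        for q in self.quadratic:
            if not (0 <= q.dim < self.n_indep):
                raise SpecError(f"quadratic term dimension {q.dim} out of range")
            if q.curvature <= 0:
                raise SpecError("quadratic curvature must be > 0")
        for bl in self.bilinear:
            i, j = bl.dims
            if not (0 <= i < self.n_indep and 0 <= j < self.n_indep and i != j):
                raise SpecError(f"bilinear dims {bl.dims} invalid")
        for m, dep in enumerate(self.dependents):
            if dep.kappa <= 0:
                raise SpecError(f"dependent {m}: stiffness kappa must be > 0")

    @property
    def n_dep(self) -> int:
        return len(self.dependents)

    @property
    def is_periodic(self) -> bool:
        """True when E is 360-degree periodic in every theta_i."""
        if self.quadratic or self.bilinear:
            return False
        return all(not dep.linear for dep in self.dependents)

    # -- evaluation --------------------------------------------------------

    def torsional_energy(self, theta: np.ndarray) -> float:
        """E_min(theta): the constrained minimum over beta at fixed theta."""
        th = np.asarray(theta, dtype=float)
        if th.shape != (self.n_indep,):
            raise SpecError(f"theta has shape {th.shape}, expected ({self.n_indep},)")
        e = 0.0
        for t in self.fourier:
            e += t.v * (1.0 - np.cos(DEG * (t.k * th[t.dim] + t.phase)))
        for c in self.coupling:
            i, j = c.dims
            e += (
                c.w
                * np.cos(DEG * (c.k[0] * th[i] + c.phases[0]))
                * np.cos(DEG * (c.k[1] * th[j] + c.phases[1]))
            )
        for bump in self.bumps:
            prof = 1.0
            for dim, c0, conc in zip(bump.dims, bump.centers, bump.conc):
                prof *= np.exp(conc * (np.cos(DEG * (th[dim] - c0)) - 1.0))
            e += bump.amp * prof
        for q in self.quadratic:
            e += 0.5 * q.curvature * (th[q.dim] - q.center) ** 2
        for bl in self.bilinear:
            i, j = bl.dims
            e += bl.w * (th[i] - bl.centers[0]) * (th[j] - bl.centers[1])
        return float(e)

    def dependent_targets(self, theta: np.ndarray) -> np.ndarray:
        """beta_hat(theta): relaxed dependent-coordinate values."""
        th = np.asarray(theta, dtype=float)
        out = np.empty(self.n_dep)
        for m, dep in enumerate(self.dependents):
            val = dep.beta0
            for s in dep.sin_terms:
                val += s.amp * np.sin(DEG * (s.k * th[s.dim] + s.phase))
            for i, coef in dep.linear:
                val += coef * th[i]
            out[m] = val
        return out

    def energy(self, theta: np.ndarray, beta: np.ndarray) -> float:
        """Full energy at (theta, beta)."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_dep,):
            raise SpecError(f"beta has shape {beta.shape}, expected ({self.n_dep},)")
        e = self.torsional_energy(theta)
        resid = beta - self.dependent_targets(theta)
        kappas = np.array([dep.kappa for dep in self.dependents])
        return float(e + 0.5 * np.sum(kappas * resid**2))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["format"] = "lamkit.potential_spec.v1"
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PotentialSpec":
        try:
            return cls(
                n_indep=int(data["n_indep"]),
                fourier=tuple(FourierTerm(**t) for t in data.get("fourier", ())),
                coupling=tuple(
                    CouplingTerm(
                        dims=tuple(c["dims"]), w=c["w"],
                        k=tuple(c.get("k", (1, 1))),
                        phases=tuple(c.get("phases", (0.0, 0.0))),
                    )
                    for c in data.get("coupling", ())
                ),
                quadratic=tuple(QuadraticTerm(**q) for q in data.get("quadratic", ())),
                bilinear=tuple(
                    BilinearTerm(dims=tuple(b["dims"]), w=b["w"],
                                 centers=tuple(b.get("centers", (0.0, 0.0))))
                    for b in data.get("bilinear", ())
                ),
                bumps=tuple(
                    BumpTerm(
                        dims=tuple(b["dims"]), amp=b["amp"],
                        centers=tuple(b["centers"]), conc=tuple(b["conc"]),
                    )
                    for b in data.get("bumps", ())
                ),
                dependents=tuple(
                    DependentModel(
                        beta0=m.get("beta0", 0.0),
                        sin_terms=tuple(SinTarget(**s) for s in m.get("sin_terms", ())),
                        linear=tuple((int(i), float(c)) for i, c in m.get("linear", ())),
                        kappa=m.get("kappa", 1.0),
                    )
                    for m in data.get("dependents", ())
                ),
                seed=data.get("seed"),
                name=data.get("name", "custom"),
            )
        except (KeyError, TypeError) as exc:
            raise SpecError(f"invalid potential spec: {exc}") from exc

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PotentialSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# constrained minimization and the oracle protocol
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    """Outcome of minimizing E over beta at fixed theta."""

    e_min: float
    beta_star: np.ndarray
    converged: bool = True
    message: str = "analytic"


@runtime_checkable
class EnergyOracle(Protocol):
    """Adapter contract for any energy engine used to build local models."""

    oracle_id: str

    @property
    def u_global(self) -> float: ...

    def constrained_minimize(self, theta: np.ndarray, tol: float = 1e-9) -> OracleResult: ...


def constrained_minimize(spec: PotentialSpec, theta: np.ndarray, tol: float = 1e-9) -> OracleResult:
    """Minimize E over the dependent coordinates at fixed theta.

    For the shipped harmonic family the minimizer is analytic:
    beta* = beta_hat(theta) and E_min is the torsional part.
    """
    beta_star = spec.dependent_targets(theta)
    return OracleResult(e_min=spec.torsional_energy(theta), beta_star=beta_star)


def global_minimum(
    spec: PotentialSpec,
    d: TorsionDomain,
    n_starts: int = 64,
    seed: int = 0,
) -> float:
    """Unconstrained global-minimum energy U_global over the domain.

    Multi-start local minimization of E_min(theta): starts are drawn from a
    coarse node grid plus seeded uniform random points, refined with L-BFGS-B
    (bounded on non-periodic dimensions; periodic ones run free and wrap).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    # coarse deterministic starts: up to 5 per dimension, capped overall
    per_dim = max(2, min(5, int(round(200 ** (1.0 / d.n)))))
    axes = [np.linspace(d.lower[i], d.upper[i], per_dim, endpoint=False) for i in range(d.n)]
    mesh = np.meshgrid(*axes, indexing="ij")
    coarse = np.stack([m.ravel() for m in mesh], axis=-1)
    if coarse.shape[0] > 128:
        coarse = coarse[rng.choice(coarse.shape[0], 128, replace=False)]
    starts.extend(coarse)
    starts.extend(d.lower + rng.random((n_starts, d.n)) * d.span)

    bounds = [
        (None, None) if d.periodic[i] else (float(d.lower[i]), float(d.upper[i]))
        for i in range(d.n)
    ]
    best = np.inf
    for x0 in starts:
        res = minimize(spec.torsional_energy, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best:
            best = float(res.fun)
    return best


class SyntheticOracle:
    """The shipped analytic oracle: a :class:`PotentialSpec` over a domain.

    U_global is computed once per (spec, domain) pair and cached; the
    intramolecular energy penalty ``delta_e(theta)`` is E_min(theta) minus
    that constant.
    """

    def __init__(
        self,
        spec: PotentialSpec,
        domain: TorsionDomain,
        oracle_id: str | None = None,
        n_starts: int = 64,
        seed: int = 0,
    ) -> None:
        self.spec = spec
        self.domain = domain
        self.oracle_id = oracle_id or f"spec:{spec.name}"
        self._n_starts = n_starts
        self._seed = seed
        self._u_global: float | None = None

    @property
    def u_global(self) -> float:
        if self._u_global is None:
            self._u_global = global_minimum(
                self.spec, self.domain, n_starts=self._n_starts, seed=self._seed
            )
        return self._u_global

    def constrained_minimize(self, theta: np.ndarray, tol: float = 1e-9) -> OracleResult:
        return constrained_minimize(self.spec, theta, tol=tol)

    def delta_e(self, theta: np.ndarray) -> float:
        """Delta_E_intra(theta) = E_min(theta) - U_global."""
        return self.constrained_minimize(theta).e_min - self.u_global


# ---------------------------------------------------------------------------
# presets and randomized generation
# ---------------------------------------------------------------------------

def quadratic_preset(
    curvature: float = 0.02, center: float = 0.0, dep_slope: float = 0.1
) -> tuple[PotentialSpec, TorsionDomain]:
    """1-D pure quadratic well: second-order local models are globally exact.

    E_min(theta) = 1/2 * curvature * (theta - center)^2; one dependent
    coordinate with linear target beta_hat = dep_slope * theta, kappa = 1.
    """
    spec = PotentialSpec(
        n_indep=1,
        quadratic=(QuadraticTerm(dim=0, curvature=curvature, center=center),),
        dependents=(DependentModel(linear=((0, dep_slope),), kappa=1.0),),
        name="quadratic",
    )
    domain = TorsionDomain([-90.0], [90.0], [False], [15.0])
    return spec, domain


def double_well_1d_preset() -> tuple[PotentialSpec, TorsionDomain]:
    """1-D double well on [-90, 90]: minima at +/-30 deg, barrier at 0.

    E_min(theta) = 20*(1 - cos 2theta) + 10*(1 + cos 4theta) kJ/mol, i.e.
    wells of depth 5 kJ/mol relative to the 0-deg barrier and ~45 kJ/mol
    walls at +/-90.  With models anchored at -90, -30, +30, +90 the
    second-order predictions from adjacent anchors disagree by ~4.3 kJ/mol
    at +/-60 deg (above the 1 kJ/mol placement threshold, below the
    20 kJ/mol relevance cutoff) and agree exactly at 0 deg by symmetry —
    the single-torsion refinement scenario this preset is frozen to re-enact.
    """
    spec = PotentialSpec(
        n_indep=1,
        fourier=(
            FourierTerm(dim=0, k=2, v=20.0),
            FourierTerm(dim=0, k=4, v=10.0, phase=180.0),
        ),
        dependents=(
            DependentModel(beta0=0.2, sin_terms=(SinTarget(dim=0, k=1, amp=0.3),), kappa=5.0),
        ),
        name="double_well_1d",
    )
    domain = TorsionDomain([-90.0], [90.0], [False], [30.0])
    return spec, domain


def coupled_2d_preset() -> tuple[PotentialSpec, TorsionDomain]:
    """2-D surface with a tilted low-energy valley and sharp localized features.

    A quadratic bowl plus a bilinear tilt forms a valley whose principal
    axes are not torsion-aligned (the torsions interact, so low-energy
    basins are non-rectangular).  Two tall, narrow repulsive cores (hard
    steric clashes, ~16-18 kJ/mol, ~10 deg wide) and one broad attractive
    pocket (an intramolecular contact, -5 kJ/mol) sit inside the valley.
    The cores are far too sharp for the coarse initial grid, so adaptive
    refinement cascades around them down to single-digit spacing, while the
    smooth background is captured exactly by any second-order model — the
    configuration that rewards placing models where the surface is rough.
    """
    spec = PotentialSpec(
        n_indep=2,
        quadratic=(
            QuadraticTerm(dim=0, curvature=0.004, center=-10.0),
            QuadraticTerm(dim=1, curvature=0.004, center=10.0),
        ),
        bilinear=(BilinearTerm(dims=(0, 1), w=0.0025, centers=(-10.0, 10.0)),),
        bumps=(
            BumpTerm(dims=(0, 1), amp=18.0, centers=(-48.0, 45.0), conc=(55.0, 50.0)),
            BumpTerm(dims=(0, 1), amp=16.0, centers=(48.0, -45.0), conc=(52.0, 57.0)),
            BumpTerm(dims=(0, 1), amp=-5.0, centers=(-8.0, 8.0), conc=(6.0, 7.0)),
        ),
        dependents=(
            DependentModel(beta0=1.0, sin_terms=(SinTarget(dim=0, k=1, amp=0.4),), kappa=3.0),
            DependentModel(
                beta0=-0.5,
                sin_terms=(SinTarget(dim=1, k=2, amp=0.25, phase=45.0),),
                kappa=2.0,
            ),
        ),
        name="coupled_2d",
    )
    domain = TorsionDomain([-120.0, -120.0], [120.0, 120.0], [False, False], [30.0, 30.0])
    return spec, domain


def random_spec(
    seed: int,
    n_indep: int = 2,
    n_dep: int = 1,
    barrier_range: tuple[float, float] = (1.0, 8.0),
    coupling_density: float = 0.5,
) -> PotentialSpec:
    """Reproducible randomized potential.

    Per dimension: 1-3 Fourier terms, multiplicity 1-3, barrier uniform in
    ``barrier_range``, phase uniform on [0, 360).  Each dimension pair gains
    a product coupling with probability ``coupling_density`` (amplitude
    uniform on [0.5, 3]).  Dependent targets are sums of 1-2 sine terms with
    stiffness uniform on [1, 5].
    """
    if barrier_range[0] <= 0 or barrier_range[1] < barrier_range[0]:
        raise SpecError("barrier_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    fourier = []
    for dim in range(n_indep):
        for _ in range(rng.integers(1, 4)):
            fourier.append(
                FourierTerm(
                    dim=dim,
                    k=int(rng.integers(1, 4)),
                    v=float(rng.uniform(*barrier_range)),
                    phase=float(rng.uniform(0.0, 360.0)),
                )
            )
    coupling = []
    for i in range(n_indep):
        for j in range(i + 1, n_indep):
            if rng.random() < coupling_density:
                coupling.append(
                    CouplingTerm(
                        dims=(i, j),
                        w=float(rng.uniform(0.5, 3.0)),
                        k=(int(rng.integers(1, 3)), int(rng.integers(1, 3))),
                        phases=(float(rng.uniform(0, 360)), float(rng.uniform(0, 360))),
                    )
                )
    dependents = []
    for _ in range(n_dep):
        sin_terms = tuple(
            SinTarget(
                dim=int(rng.integers(0, n_indep)),
                k=int(rng.integers(1, 3)),
                amp=float(rng.uniform(0.1, 0.5)),
                phase=float(rng.uniform(0, 360)),
            )
            for _ in range(rng.integers(1, 3))
        )
        dependents.append(
            DependentModel(
                beta0=float(rng.uniform(-1, 1)),
                sin_terms=sin_terms,
                kappa=float(rng.uniform(1.0, 5.0)),
            )
        )
    return PotentialSpec(
        n_indep=n_indep,
        fourier=tuple(fourier),
        coupling=tuple(coupling),
        dependents=tuple(dependents),
        seed=seed,
        name=f"random:{seed}",
    )


PRESETS = {
    "quadratic": quadratic_preset,
    "double_well_1d": double_well_1d_preset,
    "coupled_2d": coupled_2d_preset,
}


def resolve_oracle(identifier: str, domain: TorsionDomain | None = None) -> SyntheticOracle:
    """Build an oracle from a string identifier.

    ``preset:<name>`` uses a shipped preset (and its default domain unless one
    is given); ``random:<seed>`` draws a randomized 2-D spec; any other value
    is read as a path to a potential-spec JSON file (domain required).
    """
    if identifier.startswith("preset:"):
        name = identifier.split(":", 1)[1]
        if name not in PRESETS:
            raise SpecError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        spec, default_domain = PRESETS[name]()
        return SyntheticOracle(spec, domain or default_domain, oracle_id=identifier)
    if identifier.startswith("random:"):
        seed = int(identifier.split(":", 1)[1])
        spec = random_spec(seed, n_indep=domain.n if domain is not None else 2)
        if domain is None:
            domain = TorsionDomain(
                [0.0] * spec.n_indep, [360.0] * spec.n_indep,
                [True] * spec.n_indep, [30.0] * spec.n_indep,
            )
        return SyntheticOracle(spec, domain, oracle_id=identifier)
    spec = PotentialSpec.from_json(identifier)
    if domain is None:
        raise SpecError("a domain config is required with a potential-spec file")
    return SyntheticOracle(spec, domain, oracle_id=str(identifier))
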