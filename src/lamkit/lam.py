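"""Local Approximate Models (LAMs): construction, evaluation, serialization.

A LAM is a second-order model of the relaxed intramolecular energy penalty
about a reference conformation theta_ref, plus a linear model of the
dependent coordinates:

    dE(theta)   ~= E_ref + b . dtheta + 1/2 dtheta^T A dtheta
    beta(theta) ~= beta_ref + C . dtheta

with dtheta the per-dimension signed difference theta - theta_ref (shorter
arc on periodic dimensions).  b and A are derivatives of the *relaxed*
surface E_min(theta) — the dependent coordinates are re-minimized at every
finite-difference stencil point, never frozen — so the energy model is
consistent with the linear dependent-coordinate model.

A LAMSet evaluates the surface piecewise: each query point uses the LAM
whose reference conformation is nearest in the Euclidean (shorter-arc)
sense.  The piecewise surface is generally discontinuous across the midline
between two models; no smoothing is applied here, and the size of the jump
at the midline is exactly the midpoint discrepancy the adaptive placement
algorithm acts on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .space import TorsionDomain, canonicalize, distance, signed_delta

logger = logging.getLogger(__name__)

FORMAT_VERSION = "lamkit.lamset.v1"

#: LAMs closer than this (degrees) are considered duplicates
EPS_DUP = 0.5

#: reference energies below this are an error (wrong U_global); small
#: negatives above it are finite-difference noise and clamped to zero
E_REF_ABORT = -1e-6


class LAMSchemaError(ValueError):
    """A serialized LAM set violates the schema."""


class BuildError(RuntimeError):
    """LAM construction failed (oracle non-convergence or bad reference)."""


@dataclass
class LAM:
    """One local model.

    Attributes
    ----------
    theta_ref : reference conformation (degrees, canonical).
    e_ref : energy penalty dE_intra at theta_ref (kJ/mol, >= 0).
    b : gradient of the relaxed penalty (kJ/mol/deg).
    a : symmetric second-derivative matrix (kJ/mol/deg^2).
    beta_ref : dependent-coordinate values at the constrained minimum.
    c : sensitivity matrix d(beta)/d(theta) (dependent units per degree).
    payload : opaque metadata carried through serialization untouched
        (e.g. point charges or a level-of-theory tag).
    """

    theta_ref: np.ndarray
    e_ref: float
    b: np.ndarray
    a: np.ndarray
    beta_ref: np.ndarray
    c: np.ndarray
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta_ref = np.asarray(self.theta_ref, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.beta_ref = np.asarray(self.beta_ref, dtype=float)
        self.c = np.asarray(self.c, dtype=float).reshape(self.beta_ref.size, self.theta_ref.size)
        if np.max(np.abs(self.a - self.a.T), initial=0.0) > 1e-9:
            raise LAMSchemaError("second-derivative matrix A is not symmetric within 1e-9")
        if self.e_ref < E_REF_ABORT:
            raise BuildError(
                f"reference energy {self.e_ref} is significantly negative; "
                "the global-minimum constant U_global is inconsistent with this oracle"
            )
        if self.e_ref < 0.0:
            logger.warning("clamping slightly negative e_ref %.3e to 0", self.e_ref)
            self.e_ref = 0.0


def build_lam(oracle, theta_ref: np.ndarray, domain: TorsionDomain,
              fd_step: float = 1.0, tol: float = 1e-9, payload: dict | None = None) -> LAM:
    """Build a LAM at theta_ref by central finite differences.

    The oracle's ``constrained_minimize`` is called at the reference point
    and at stencil points displaced by ``fd_step`` degrees: 3-point stencils
    give the gradient and diagonal curvatures, 4-point cross stencils the
    off-diagonal curvatures, and the same displacements differentiate the
    relaxed dependent coordinates for the sensitivity matrix C.  A is
    symmetrized after assembly.
    """
    theta_ref = canonicalize(np.asarray(theta_ref, dtype=float), domain)
    if not domain.contains(theta_ref):
        raise BuildError(f"reference conformation {theta_ref} is outside the domain")
    n = domain.n
    h = float(fd_step)

    def probe(displacement: np.ndarray):
        res = oracle.constrained_minimize(theta_ref + displacement, tol=tol)
        if not res.converged:
            raise BuildError(
                f"constrained minimization failed at {theta_ref + displacement}: {res.message}"
            )
        return res

    r0 = probe(np.zeros(n))
    e0 = r0.e_min
    m = r0.beta_star.size

    e_plus = np.empty(n)
    e_minus = np.empty(n)
    beta_plus = np.empty((n, m))
    beta_minus = np.empty((n, m))
    for i in range(n):
        step = np.zeros(n)
        step[i] = h
        rp, rm = probe(step), probe(-step)
        e_plus[i], e_minus[i] = rp.e_min, rm.e_min
        beta_plus[i], beta_minus[i] = rp.beta_star, rm.beta_star

    b = (e_plus - e_minus) / (2.0 * h)
    a = np.zeros((n, n))
    np.fill_diagonal(a, (e_plus - 2.0 * e0 + e_minus) / h**2)
    for i in range(n):
        for j in range(i + 1, n):
            step = np.zeros(n)
            step[i] = h
            step[j] = h
            epp = probe(step).e_min
            step[j] = -h
            epm = probe(step).e_min
            step[i] = -h
            emm = probe(step).e_min
            step[j] = h
            emp = probe(step).e_min
            a[i, j] = a[j, i] = (epp - epm - emp + emm) / (4.0 * h**2)
    a = 0.5 * (a + a.T)
    c = (beta_plus - beta_minus).T / (2.0 * h)

    return LAM(
        theta_ref=theta_ref,
        e_ref=e0 - oracle.u_global,
        b=b,
        a=a,
        beta_ref=r0.beta_star,
        c=c,
        payload=payload or {},
    )


def evaluate_lam(lam: LAM, theta: np.ndarray, d: TorsionDomain) -> tuple[float, np.ndarray]:
    """Second-order energy and linear dependent-coordinate prediction."""
    dtheta = signed_delta(d.check_vector(theta), lam.theta_ref, d)
    de = lam.e_ref + lam.b @ dtheta + 0.5 * dtheta @ lam.a @ dtheta
    beta = lam.beta_ref + lam.c @ dtheta
    return float(de), beta


@dataclass
class LAMSet:
    """An ordered collection of LAMs over one domain; the unit of I/O.

    ``provenance`` records the oracle identifier, the cached U_global
    constant, the build parameters, and a free-form creation log.
    """

    domain: TorsionDomain
    lams: list[LAM] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lams)

    def add(self, lam: LAM, eps_dup: float = EPS_DUP) -> None:
        """Append a LAM, refusing near-duplicate reference conformations."""
        for k, existing in enumerate(self.lams):
            if distance(existing.theta_ref, lam.theta_ref, self.domain) < eps_dup:
                raise ValueError(
                    f"new reference {lam.theta_ref} duplicates LAM {k} within {eps_dup} deg"
                )
        self.lams.append(lam)

    def nearest(self, theta: np.ndarray) -> tuple[int, LAM]:
        """Index and LAM with the nearest reference; ties -> lowest index."""
        if not self.lams:
            raise ValueError("LAM set is empty")
        theta = self.domain.check_vector(theta)
        dists = np.array([distance(l.theta_ref, theta, self.domain) for l in self.lams])
        idx = int(np.argmin(dists))
        return idx, self.lams[idx]

    def evaluate(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Piecewise (nearest-LAM) energy-penalty and dependent prediction."""
        _, lam = self.nearest(theta)
        return evaluate_lam(lam, theta, self.domain)

    def evaluate_with_id(self, theta: np.ndarray) -> tuple[float, np.ndarray, int]:
        idx, lam = self.nearest(theta)
        de, beta = evaluate_lam(lam, theta, self.domain)
        return de, beta, idx


def nearest_lam(ls: LAMSet, theta: np.ndarray) -> LAM:
    return ls.nearest(theta)[1]


def build_grid_lamset(oracle, domain: TorsionDomain, points, fd_step: float = 1.0,
                      tol: float = 1e-9) -> LAMSet:
    """Build a LAMSet with one model at each of the given conformations."""
    ls = LAMSet(
        domain=domain,
        provenance={
            "oracle_id": getattr(oracle, "oracle_id", "unknown"),
            "u_global": float(oracle.u_global),
            "build_params": {"fd_step": fd_step, "tol": tol},
            "log": [f"grid build: {len(points)} points"],
        },
    )
    for pt in points:
        ls.add(build_lam(oracle, pt, domain, fd_step=fd_step, tol=tol))
    return ls


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_LAM_FIELDS = {"theta_ref", "e_ref", "b", "a", "beta_ref", "c", "payload"}


def write_lamset(ls: LAMSet, path) -> None:
    """Write a LAMSet as JSON; floats use full repr precision."""
    doc = {
        "format_version": FORMAT_VERSION,
        "domain": ls.domain.to_dict(),
        "u_global": ls.provenance.get("u_global"),
        "oracle_id": ls.provenance.get("oracle_id"),
        "build_params": ls.provenance.get("build_params", {}),
        "log": ls.provenance.get("log", []),
        "lams": [
            {
                "theta_ref": lam.theta_ref.tolist(),
                "e_ref": lam.e_ref,
                "b": lam.b.tolist(),
                "a": lam.a.tolist(),
                "beta_ref": lam.beta_ref.tolist(),
                "c": lam.c.tolist(),
                "payload": lam.payload,
            }
            for lam in ls.lams
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise LAMSchemaError(f"{where}: missing required field {key!r}")
    return doc[key]


def read_lamset(path) -> LAMSet:
    """Read and validate a LAMSet JSON file.

    Unknown extra fields on a LAM record are folded into its payload (and
    logged); structural violations raise :class:`LAMSchemaError` naming the
    offending field.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise LAMSchemaError(f"not valid JSON: {exc}") from exc
    if doc.get("format_version") != FORMAT_VERSION:
        raise LAMSchemaError(
            f"format_version: expected {FORMAT_VERSION!r}, got {doc.get('format_version')!r}"
        )
    from .space import DomainError

    try:
        domain = TorsionDomain.from_dict(_require(doc, "domain", "lamset"))
    except DomainError as exc:
        raise LAMSchemaError(f"domain: {exc}") from exc
    ls = LAMSet(
        domain=domain,
        provenance={
            "oracle_id": doc.get("oracle_id"),
            "u_global": doc.get("u_global"),
            "build_params": doc.get("build_params", {}),
            "log": doc.get("log", []),
        },
    )
    for k, rec in enumerate(_require(doc, "lams", "lamset")):
        where = f"lams[{k}]"
        extras = {key: rec[key] for key in rec.keys() - _LAM_FIELDS}
        payload = dict(rec.get("payload", {}))
        if extras:
            logger.info("%s: folding unknown fields %s into payload", where, sorted(extras))
            payload.update(extras)
        try:
            lam = LAM(
                theta_ref=_require(rec, "theta_ref", where),
                e_ref=float(_require(rec, "e_ref", where)),
                b=_require(rec, "b", where),
                a=_require(rec, "a", where),
                beta_ref=rec.get("beta_ref", []),
                c=rec.get("c", []),
                payload=payload,
            )
        except (LAMSchemaError, BuildError) as exc:
            raise LAMSchemaError(f"{where}: {exc}") from exc
        if not domain.contains(canonicalize(lam.theta_ref, domain)):
            raise LAMSchemaError(f"{where}.theta_ref: {lam.theta_ref} outside domain")
        ls.lams.append(lam)
    return ls
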