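"""Adaptive LAM placement by midpoint discrepancy.

Given an existing set of local models, every unordered pair (A, B) is a
candidate for refinement at the conformational midpoint M of its reference
points.  A new model is generated at M only when all of the following hold:

* **discrepancy** — the two models' energy predictions at M differ by more
  than the threshold ``delta_e`` (default 1 kJ/mol, strict);
* **relevance** — the lower of the two predictions is at most the cutoff
  ``cutoff`` (default 20 kJ/mol): conformations costing more than that are
  not expected to occur in real polymorphs, so accuracy there is wasted;
* **nearest** — no third model is strictly nearer to M than A and B are
  (otherwise neither A nor B would ever be consulted at M, and their
  disagreement there is moot).

Pairs whose midpoint is ambiguous (antipodal on a periodic dimension) or
falls within ``eps_dup`` of an existing model are skipped.  In
``single_pass`` mode all pairs of the *initial* set are examined once
(additions during the pass only participate in the duplicate check); in
``iterate`` mode whole sweeps repeat over the growing set until a sweep
accepts nothing.  Termination is guaranteed by the duplicate threshold: only
finitely many points at pairwise distance >= eps_dup fit in the compact
search domain.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .lam import EPS_DUP, LAM, LAMSet, build_lam, evaluate_lam
from .space import AntipodalPairError, TorsionDomain, distance, midpoint

logger = logging.getLogger(__name__)


class BudgetExhausted(RuntimeError):
    """The safety budget on new models was reached before convergence."""


@dataclass(frozen=True)
class AdaptParams:
    """Tunables of the placement algorithm.

    ``delta_e`` and ``cutoff`` are the two energy thresholds (kJ/mol);
    ``mode`` selects single-pass or iterate-to-fixed-point refinement;
    ``max_new_lams`` is a hard safety budget; ``pair_scope`` may restrict
    candidate pairs to those within ``radius`` degrees of each other (a
    performance guard only — distant pairs are rejected by the nearest-model
    criterion anyway).
    """

    delta_e: float = 1.0
    cutoff: float = 20.0
    mode: str = "iterate"
    max_new_lams: int = 1000
    pair_scope: str = "all"
    radius: float | None = None
    eps_dup: float = EPS_DUP
    fd_step: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_e <= 0 or self.cutoff <= 0:
            raise ValueError("delta_e and cutoff must be > 0")
        if self.mode not in ("single_pass", "iterate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.pair_scope not in ("all", "within_radius"):
            raise ValueError(f"unknown pair_scope {self.pair_scope!r}")
        if self.pair_scope == "within_radius" and not self.radius:
            raise ValueError("pair_scope='within_radius' requires a radius")


@dataclass
class PlacementDecision:
    """Outcome of examining one model pair.

    ``blocking`` is one of ``discrepancy``, ``cutoff``, ``nearer_lam``,
    ``antipodal``, ``duplicate`` when rejected, else None.
    """

    pair: tuple[int, int]
    midpoint: np.ndarray | None
    discrepancy: float | None
    min_pred_energy: float | None
    accepted: bool
    blocking: str | None = None
    sweep: int = 0

    def as_row(self) -> dict:
        mid = None if self.midpoint is None else "/".join(f"{x:.6g}" for x in self.midpoint)
        return {
            "pair_a": self.pair[0],
            "pair_b": self.pair[1],
            "midpoint": mid,
            "discrepancy": self.discrepancy,
            "min_pred_energy": self.min_pred_energy,
            "outcome": "accepted" if self.accepted else "rejected",
            "blocking_criterion": self.blocking or "",
            "sweep": self.sweep,
        }


@dataclass
class AdaptResult:
    lamset: LAMSet
    decisions: list[PlacementDecision]
    n_added: int
    sweeps: int
    converged: bool


def _dists_to(refs: np.ndarray, point: np.ndarray, domain: TorsionDomain) -> np.ndarray:
    """Distances (shorter-arc per periodic dimension) from many refs to one point."""
    delta = refs - point
    per = domain.periodic
    if per.any():
        delta[:, per] = np.mod(delta[:, per] + 180.0, 360.0) - 180.0
    return np.sqrt((delta * delta).sum(axis=1))


def check_pair(
    base: list[LAM],
    ia: int,
    ib: int,
    params: AdaptParams,
    domain: TorsionDomain,
    current: list[LAM] | None = None,
    current_refs: np.ndarray | None = None,
) -> PlacementDecision:
    """Decide whether to place a model at the midpoint of pair (ia, ib).

    ``base`` is the set the decision criteria are evaluated against;
    ``current`` (defaulting to ``base``) additionally holds models added
    earlier in the same pass — it must extend ``base`` in order — and is
    consulted only for the duplicate check.  ``current_refs`` is an optional
    pre-stacked reference array (a sweep-loop optimisation).
    Criteria are evaluated cheapest-first (nearest-model, then relevance,
    then discrepancy); acceptance requires all three, so the order cannot
    change outcomes, only which blocking criterion is reported.
    """
    if ia == ib:
        raise ValueError("a pair must consist of two distinct models")
    if current is None:
        current = base
    A, B = base[ia], base[ib]
    try:
        mid = midpoint(A.theta_ref, B.theta_ref, domain)
    except AntipodalPairError:
        logger.debug("pair (%d, %d) is antipodal; skipping", ia, ib)
        return PlacementDecision((ia, ib), None, None, None, False, "antipodal")

    if current_refs is None:
        current_refs = np.stack([lam.theta_ref for lam in current])
    d_current = _dists_to(current_refs, mid, domain)
    d_current[[ia, ib]] = np.inf
    if d_current.min() < params.eps_dup:
        return PlacementDecision((ia, ib), mid, None, None, False, "duplicate")

    d_pair = distance(A.theta_ref, mid, domain)
    if d_current[: len(base)].min() < d_pair:  # strict: ties do not block
        return PlacementDecision((ia, ib), mid, None, None, False, "nearer_lam")

    de_a, _ = evaluate_lam(A, mid, domain)
    de_b, _ = evaluate_lam(B, mid, domain)
    disc = abs(de_a - de_b)
    min_pred = min(de_a, de_b)
    if min_pred > params.cutoff:
        return PlacementDecision((ia, ib), mid, disc, min_pred, False, "cutoff")
    if disc <= params.delta_e:  # acceptance requires a strict excess
        return PlacementDecision((ia, ib), mid, disc, min_pred, False, "discrepancy")
    return PlacementDecision((ia, ib), mid, disc, min_pred, True)


def _sweep(
    ls: LAMSet, oracle, params: AdaptParams, sweep_no: int, budget_left: int
) -> tuple[int, list[PlacementDecision], bool]:
    """One pass over all pairs of the current set; returns (added, log, hit_budget)."""
    base = list(ls.lams)
    refs = np.stack([lam.theta_ref for lam in ls.lams])
    decisions: list[PlacementDecision] = []
    added = 0
    for ia, ib in itertools.combinations(range(len(base)), 2):
        if params.pair_scope == "within_radius":
            if distance(base[ia].theta_ref, base[ib].theta_ref, ls.domain) > params.radius:
                continue
        dec = check_pair(base, ia, ib, params, ls.domain, current=ls.lams, current_refs=refs)
        dec.sweep = sweep_no
        decisions.append(dec)
        if dec.accepted:
            if added >= budget_left:
                dec.accepted = False
                dec.blocking = "budget"
                return added, decisions, True
            lam = build_lam(oracle, dec.midpoint, ls.domain, fd_step=params.fd_step)
            ls.add(lam, eps_dup=params.eps_dup)
            refs = np.vstack([refs, lam.theta_ref[None]])
            added += 1
    return added, decisions, False


def adapt(ls: LAMSet, oracle, params: AdaptParams | None = None) -> AdaptResult:
    """Refine a LAM set by midpoint placement; returns set + decision log.

    The input set is not modified.  ``single_pass`` examines pairs of the
    initial set once; ``iterate`` repeats sweeps over the current set until
    a sweep adds nothing.  If ``max_new_lams`` is exhausted the partial
    result is returned with ``converged=False``.
    """
    if not ls.lams:
        raise ValueError("cannot adapt an empty LAM set")
    params = params or AdaptParams()
    out = LAMSet(domain=ls.domain, lams=list(ls.lams), provenance=dict(ls.provenance))
    decisions: list[PlacementDecision] = []
    total_added = 0
    sweeps = 0
    converged = True
    while True:
        sweeps += 1
        added, log, hit_budget = _sweep(
            out, oracle, params, sweeps, params.max_new_lams - total_added
        )
        decisions.extend(log)
        total_added += added
        if hit_budget:
            converged = False
            logger.warning("adaptation stopped: budget of %d new models reached", params.max_new_lams)
            break
        if params.mode == "single_pass" or added == 0:
            break
    out.provenance.setdefault("log", []).append(
        f"adapt mode={params.mode} delta_e={params.delta_e} cutoff={params.cutoff}: "
        f"added {total_added} models in {sweeps} sweep(s), converged={converged}"
    )
    return AdaptResult(out, decisions, total_added, sweeps, converged)


def residual_violations(ls: LAMSet, params: AdaptParams | None = None) -> list[PlacementDecision]:
    """Post-hoc audit: pairs meeting relevance+nearest whose discrepancy still exceeds delta_e.

    After iterate-mode adaptation this list is expected to be empty (the
    convergence post-condition of the fixed-point sweep).
    """
    params = params or AdaptParams()
    bad = []
    base = list(ls.lams)
    for ia, ib in itertools.combinations(range(len(base)), 2):
        dec = check_pair(base, ia, ib, params, ls.domain)
        if dec.accepted:
            bad.append(dec)
    return bad


def expand_domain(
    oracle,
    d: TorsionDomain,
    threshold: float = 15.0,
    increment: float = 30.0,
    max_span: float = 360.0,
) -> tuple[TorsionDomain, dict]:
    """Grow non-periodic edges while the edge energy penalty stays low.

    For each bounded dimension, the energy penalty dE_intra is probed at the
    edge (other coordinates held at the domain centre); while it is below
    ``threshold`` kJ/mol and the span is below ``max_span`` (capped at 360),
    that edge is pushed outward by ``increment`` degrees.  Periodic
    dimensions already cover the circle and are left untouched.  Returns the
    final domain and a per-edge trajectory log.
    """
    if increment <= 0:
        raise ValueError("increment must be > 0")
    max_span = min(max_span, 360.0)
    lower = d.lower.copy()
    upper = d.upper.copy()
    log: dict = {"threshold": threshold, "increment": increment, "edges": []}

    for i in range(d.n):
        if d.periodic[i]:
            log["edges"].append({"dim": i, "name": d.names[i], "skipped": "periodic"})
            continue
        for side, sign in (("lower", -1.0), ("upper", +1.0)):
            traj = []
            capped = False
            while True:
                edge = d.center().copy()
                edge[i] = lower[i] if side == "lower" else upper[i]
                de = oracle.constrained_minimize(edge).e_min - oracle.u_global
                traj.append({"edge": float(edge[i]), "delta_e": float(de)})
                if de >= threshold:
                    break
                if upper[i] - lower[i] + increment > max_span + 1e-9:
                    capped = True
                    logger.warning(
                        "dimension %d (%s) %s edge: span cap %g deg reached with edge "
                        "energy %.3g below threshold %g", i, d.names[i], side, max_span, de, threshold,
                    )
                    break
                if side == "lower":
                    lower[i] -= increment
                else:
                    upper[i] += increment
            log["edges"].append(
                {"dim": i, "name": d.names[i], "side": side, "trajectory": traj, "capped": capped}
            )

    new = TorsionDomain(lower, upper, d.periodic.copy(), d.half_spacing.copy(), d.names)
    return new, log
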