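"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain Python loops and ``math`` so that it
shares no geometry or sweep code with the package; only LAM *construction*
(finite differencing against the energy oracle) is delegated to the package,
since the reference checks placement decisions, not derivative stencils.
"""

from __future__ import annotations

import itertools
import math


def ref_delta(a: float, b: float, periodic: bool) -> float:
    d = a - b
    if periodic:
        while d <= -180.0:
            d += 360.0
        while d > 180.0:
            d -= 360.0
    return d


def ref_distance(a, b, periodic_flags) -> float:
    return math.sqrt(
        sum(ref_delta(x, y, p) ** 2 for x, y, p in zip(a, b, periodic_flags))
    )


def ref_midpoint(a, b, lower, upper, periodic_flags):
    out = []
    for x, y, lo, up, p in zip(a, b, lower, upper, periodic_flags):
        d = ref_delta(x, y, p)
        if p and abs(abs(d) - 180.0) <= 1e-9:
            return None  # antipodal
        m = y + 0.5 * d
        if p:
            while m < lo:
                m += 360.0
            while m >= up:
                m -= 360.0
        out.append(m)
    return out


def ref_eval_lam(lam, theta, periodic_flags) -> float:
    """Quadratic-form evaluation with explicit loops over stored numbers."""
    n = len(theta)
    d = [ref_delta(theta[i], float(lam.theta_ref[i]), periodic_flags[i]) for i in range(n)]
    val = float(lam.e_ref)
    for i in range(n):
        val += float(lam.b[i]) * d[i]
        for j in range(n):
            val += 0.5 * d[i] * float(lam.a[i][j]) * d[j]
    return val


def ref_check_pair(base, ia, ib, domain, current, delta_e, cutoff, eps_dup):
    """Reference placement decision; returns (accepted, blocking, midpoint)."""
    lower = [float(x) for x in domain.lower]
    upper = [float(x) for x in domain.upper]
    per = [bool(x) for x in domain.periodic]
    A, B = base[ia], base[ib]
    ta = [float(x) for x in A.theta_ref]
    tb = [float(x) for x in B.theta_ref]
    mid = ref_midpoint(ta, tb, lower, upper, per)
    if mid is None:
        return False, "antipodal", None
    for lam in current:
        if lam is A or lam is B:
            continue
        if ref_distance([float(x) for x in lam.theta_ref], mid, per) < eps_dup:
            return False, "duplicate", mid
    d_pair = ref_distance(ta, mid, per)
    for k, lam in enumerate(base):
        if k in (ia, ib):
            continue
        if ref_distance([float(x) for x in lam.theta_ref], mid, per) < d_pair:
            return False, "nearer_lam", mid
    ea = ref_eval_lam(A, mid, per)
    eb = ref_eval_lam(B, mid, per)
    if min(ea, eb) > cutoff:
        return False, "cutoff", mid
    if abs(ea - eb) <= delta_e:
        return False, "discrepancy", mid
    return True, None, mid


def ref_adapt(lamset, oracle, mode="iterate", delta_e=1.0, cutoff=20.0,
              eps_dup=0.5, fd_step=1.0, max_new=1000):
    """Reference sweep loop; LAM construction is delegated to the package.

    Returns (final reference list, decision log of
    (pair, accepted, blocking) tuples in evaluation order).
    """
    from lamkit.lam import build_lam

    domain = lamset.domain
    current = list(lamset.lams)
    log = []
    added_total = 0
    while True:
        base = list(current)
        added = 0
        for ia, ib in itertools.combinations(range(len(base)), 2):
            accepted, blocking, mid = ref_check_pair(
                base, ia, ib, domain, current, delta_e, cutoff, eps_dup
            )
            if accepted and added_total >= max_new:
                accepted, blocking = False, "budget"
            log.append(((ia, ib), accepted, blocking, mid))
            if accepted:
                import numpy as np

                current.append(build_lam(oracle, np.array(mid), domain, fd_step=fd_step))
                added += 1
                added_total += 1
        if mode == "single_pass" or added == 0:
            break
    return current, log


def brute_min_over_beta(spec, theta, lo=-6.0, hi=6.0, n=4801):
    """Dense-grid scan over the dependent coordinates.

    The dependent part of the energy is separable (one harmonic per
    coordinate), so each beta_m can be scanned independently.
    """
    import numpy as np

    theta = np.asarray(theta, dtype=float)
    betas = [lo + (hi - lo) * i / (n - 1) for i in range(n)]
    best = []
    for m in range(spec.n_dep):
        vals = []
        for b in betas:
            probe = np.zeros(spec.n_dep)
            probe[m] = b
            vals.append(spec.energy(theta, probe))
        best.append(betas[vals.index(min(vals))])
    return spec.energy(theta, np.array(best)), best
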