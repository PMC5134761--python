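"""Canned study protocols: the end-to-end experiments the package ships.

Each function runs one self-contained experiment on the shipped synthetic
fixtures and returns a flat dict of the quantities it measured.  They are
the programmatic counterparts of the CLI ``demo`` commands and are what the
acceptance script re-runs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .adapt import AdaptParams, adapt, residual_violations
from .analysis import min_spacing, scan, summarize
from .lam import build_grid_lamset, build_lam, evaluate_lam
from .oracle import SyntheticOracle, double_well_1d_preset, quadratic_preset, coupled_2d_preset
from .space import TorsionDomain, regular_grid


def example_domain_7d_fine() -> TorsionDomain:
    """Seven-torsion search space, +/-15 deg cells throughout.

    Two full-circle torsions and five bounded ones; the cell-centred grid
    over it has 12*1*3*2*3*1*12 = 2592 points.
    """
    return TorsionDomain(
        lower=[0, 165, 95, 55, 95, 165, 0],
        upper=[360, 195, 185, 115, 185, 195, 360],
        periodic=[True, False, False, False, False, False, True],
        half_spacing=[15] * 7,
    )


def example_domain_7d_coarse() -> TorsionDomain:
    """Extended seven-torsion search space with a coarse initial grid.

    The two wide bounded torsions span [20, 260] at +/-30 deg; the
    cell-centred grid has 6*1*4*2*4*1*6 = 1152 points.
    """
    return TorsionDomain(
        lower=[0, 165, 20, 55, 20, 165, 0],
        upper=[360, 195, 260, 115, 260, 195, 360],
        periodic=[True, False, False, False, False, False, True],
        half_spacing=[30, 15, 30, 15, 30, 15, 30],
    )


def grid_counts() -> dict:
    """Cell-centred / node grid sizes of the shipped example domains."""
    one_d = TorsionDomain([-90.0], [90.0], [False], [15.0])
    return {
        "grid_points_7d_fine": len(regular_grid(example_domain_7d_fine(), "centered")),
        "grid_points_7d_coarse": len(regular_grid(example_domain_7d_coarse(), "centered")),
        "grid_points_1d_nodes": len(regular_grid(one_d, "nodes")),
    }


def quadratic_exactness() -> dict:
    """Exactness of second-order models on the pure quadratic well."""
    spec, domain = quadratic_preset()
    oracle = SyntheticOracle(spec, domain, "preset:quadratic")
    ls = build_grid_lamset(oracle, domain, regular_grid(domain, "centered"))
    emap = scan(ls, oracle, increment=1.0)
    added = {
        mode: adapt(ls, oracle, AdaptParams(mode=mode)).n_added
        for mode in ("single_pass", "iterate")
    }
    return {
        "max_abs_error": float(emap.table.abs_error.max()),
        "n_lams": len(ls),
        "added_single_pass": added["single_pass"],
        "added_iterate": added["iterate"],
        "n_scan_points": len(emap),
    }


def single_torsion_refinement() -> dict:
    """Refinement of the 1-D double well from four node-grid models.

    Adjacent second-order models disagree by ~4.3 kJ/mol at +/-60 deg and
    agree exactly at the symmetric barrier (0 deg), so exactly two models
    are inserted and the final set has six.
    """
    spec, domain = double_well_1d_preset()
    oracle = SyntheticOracle(spec, domain, "preset:double_well_1d")
    points = regular_grid(domain, "nodes")  # -90, -30, +30, +90
    ls = build_grid_lamset(oracle, domain, points)
    result = adapt(ls, oracle, AdaptParams(mode="iterate"))
    new_refs = sorted(float(l.theta_ref[0]) for l in result.lamset.lams[len(points):])
    accepted = [d for d in result.decisions if d.accepted]
    return {
        "n_initial": len(points),
        "n_added": result.n_added,
        "n_final": len(result.lamset),
        "new_refs": new_refs,
        "midpoint_discrepancy": float(max(d.discrepancy for d in accepted)) if accepted else 0.0,
        "has_model_at_barrier": any(abs(r) < 1.0 for r in new_refs),
    }


def _dense_comparison_grid(domain: TorsionDomain, n_target: int) -> TorsionDomain:
    """Smallest centred regular grid over the domain with >= n_target points."""
    cells = math.ceil(n_target ** (1.0 / domain.n))
    half = domain.span / (2.0 * cells)
    return dataclasses.replace(domain, half_spacing=half)


def coupled_refinement(scan_increment: float = 2.0, max_new_lams: int = 400) -> dict:
    """Iterate-mode refinement of the coupled 2-D fixture, with error maps.

    Scans the piecewise surface against the oracle on a dense grid (2 deg by
    default: the sharp localized features are ~10 deg wide) for the initial
    coarse grid, the adapted set, and a centred regular grid holding at
    least three times as many models as the adapted set.
    """
    spec, domain = coupled_2d_preset()
    oracle = SyntheticOracle(spec, domain, "preset:coupled_2d")
    ls = build_grid_lamset(oracle, domain, regular_grid(domain, "centered"))
    result = adapt(ls, oracle, AdaptParams(mode="iterate", max_new_lams=max_new_lams))

    dense_domain = _dense_comparison_grid(domain, 3 * len(result.lamset))
    dense = build_grid_lamset(oracle, dense_domain, regular_grid(dense_domain, "centered"))

    s_init = summarize(scan(ls, oracle, scan_increment))
    s_adapt = summarize(scan(result.lamset, oracle, scan_increment))
    s_dense = summarize(scan(dense, oracle, scan_increment))
    return {
        "n_initial": len(ls),
        "n_added": result.n_added,
        "n_final": len(result.lamset),
        "n_sweeps": result.sweeps,
        "converged": result.converged,
        "min_spacing": float(min_spacing(result.lamset)),
        "n_dense": len(dense),
        "mae_initial": s_init["mean_abs_dev"],
        "mae_adapted": s_adapt["mean_abs_dev"],
        "mae_dense": s_dense["mean_abs_dev"],
        "max_err_initial": s_init["max_abs_error"],
        "max_err_adapted": s_adapt["max_abs_error"],
        "max_err_dense": s_dense["max_abs_error"],
        "residual_violations": len(residual_violations(result.lamset)),
        "n_scan_points": s_adapt["n_points"],
    }


def taylor_order_ratios(theta_ref: float = 45.0) -> dict:
    """Decay of the max in-cell model error as the cell half-width is halved.

    A second-order model of a smooth surface carries a third-order Taylor
    remainder, so the worst error inside a +/-h cell scales like h^3: each
    halving of h should shrink it ~8x (asserted loosely at >= 3x).
    """
    spec, domain = double_well_1d_preset()
    oracle = SyntheticOracle(spec, domain, "preset:double_well_1d")
    ref = np.array([theta_ref])
    lam = build_lam(oracle, ref, domain)

    def max_err(half_width: float) -> float:
        return max(
            abs(evaluate_lam(lam, ref + h, domain)[0] - oracle.delta_e(ref + h))
            for h in np.linspace(-half_width, half_width, 129)
        )

    e16, e8, e4 = max_err(16.0), max_err(8.0), max_err(4.0)
    return {
        "max_err_16": e16,
        "max_err_8": e8,
        "max_err_4": e4,
        "ratio_16_8": e16 / e8,
        "ratio_8_4": e8 / e4,
    }
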