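"""Quantitative comparison of a LAM surface against its oracle.

The central object is an :class:`ErrorMap`: a dense scan of the piecewise
LAM surface and the oracle's relaxed energy penalty over a (sub-)domain,
tabulating the absolute difference point by point together with the identity
of the nearest model at each point.  Summary statistics condense a map into
the numbers usually quoted for surrogate quality: mean absolute deviation,
worst-case error and where it occurs, and the fraction of the scanned space
with error above a materiality threshold (5 kJ/mol by default).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lam import LAMSet
from .space import DomainError, TorsionDomain, distance


@dataclass
class ErrorMap:
    """Tabulated LAM-vs-oracle differences over a scan grid.

    ``table`` columns: one ``theta_<name>`` per scanned dimension,
    ``de_lam``, ``de_oracle``, ``abs_error``, ``nearest_lam_id``.
    ``meta`` records the increment, fixed-slice values and oracle identity
    so a map (and any plot of it) is reproducible from the files alone.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path, meta_path=None) -> None:
        self.table.to_csv(path, index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(self.meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "ErrorMap":
        meta = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(pd.read_csv(path), meta)


def _scan_axis(lo: float, up: float, increment: float, periodic: bool) -> np.ndarray:
    span = up - lo
    steps = span / increment
    if abs(steps - round(steps)) > 1e-9:
        raise DomainError(f"scan increment {increment} does not divide span {span}")
    steps = int(round(steps))
    return lo + increment * np.arange(steps if periodic else steps + 1)


def scan(
    ls: LAMSet,
    oracle,
    increment: float,
    sub_domain: TorsionDomain | None = None,
    fixed: dict[int, float] | None = None,
) -> ErrorMap:
    """Scan LAM and oracle energies on a node grid of the (sub-)domain.

    ``fixed`` maps dimension indices to constant values, producing a slice;
    the remaining (free) dimensions are scanned from bound to bound in
    ``increment``-degree steps (the wrap point is omitted on periodic
    dimensions).  The scan always evaluates the full LAM set of the full
    domain — only the probing grid is restricted.
    """
    d = sub_domain or ls.domain
    fixed = fixed or {}
    free = [i for i in range(d.n) if i not in fixed]
    if not free:
        raise ValueError("at least one dimension must be scanned")
    axes = [_scan_axis(d.lower[i], d.upper[i], increment, bool(d.periodic[i])) for i in free]

    names = ls.domain.names
    rows = []
    base = np.array([fixed.get(i, 0.0) for i in range(d.n)])
    for combo in itertools.product(*axes):
        theta = base.copy()
        theta[free] = combo
        de_lam, _, idx = ls.evaluate_with_id(theta)
        de_orc = oracle.constrained_minimize(theta).e_min - oracle.u_global
        row = {f"theta_{names[i]}": theta[i] for i in range(d.n)}
        row.update(
            de_lam=de_lam, de_oracle=de_orc, abs_error=abs(de_lam - de_orc), nearest_lam_id=idx
        )
        rows.append(row)

    meta = {
        "increment": increment,
        "fixed": {int(k): float(v) for k, v in fixed.items()},
        "oracle_id": getattr(oracle, "oracle_id", "unknown"),
        "n_lams": len(ls),
        "n_points": len(rows),
    }
    return ErrorMap(pd.DataFrame(rows), meta)


def summarize(emap: ErrorMap, threshold: float = 5.0) -> dict:
    """Summary statistics of an error map.

    Returns mean_abs_dev, max_abs_error, argmax_theta (the scanned point of
    worst error) and frac_above (share of rows with abs_error > threshold).
    """
    if len(emap) == 0:
        raise ValueError("error map is empty")
    err = emap.table["abs_error"].to_numpy()
    imax = int(np.argmax(err))
    theta_cols = [c for c in emap.table.columns if c.startswith("theta_")]
    return {
        "mean_abs_dev": float(err.mean()),
        "max_abs_error": float(err[imax]),
        "argmax_theta": emap.table.iloc[imax][theta_cols].to_numpy(dtype=float).tolist(),
        "frac_above": float((err > threshold).mean()),
        "threshold": threshold,
        "n_points": int(err.size),
    }


def min_spacing(ls: LAMSet) -> float:
    """Minimum pairwise distance (degrees) between model reference points."""
    if len(ls) < 2:
        raise ValueError("min_spacing requires at least 2 models")
    refs = [lam.theta_ref for lam in ls.lams]
    return min(
        distance(a, b, ls.domain) for a, b in itertools.combinations(refs, 2)
    )


def plot_error_map(emap: ErrorMap, path) -> None:
    """Render a 1-D profile or 2-D heat map of the absolute error (PNG etc.)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta_cols = [c for c in emap.table.columns if c.startswith("theta_")]
    varying = [c for c in theta_cols if emap.table[c].nunique() > 1]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if len(varying) == 1:
        ax.plot(emap.table[varying[0]], emap.table["abs_error"], lw=1.2)
        ax.set_xlabel(f"{varying[0]} (deg)")
        ax.set_ylabel("|LAM - oracle| (kJ/mol)")
    elif len(varying) == 2:
        x, y = varying
        piv = emap.table.pivot_table(index=y, columns=x, values="abs_error")
        im = ax.pcolormesh(piv.columns, piv.index, piv.values, shading="auto")
        fig.colorbar(im, ax=ax, label="|LAM - oracle| (kJ/mol)")
        ax.set_xlabel(f"{x} (deg)")
        ax.set_ylabel(f"{y} (deg)")
    else:
        raise ValueError("plotting supports 1-D or 2-D scans only")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
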