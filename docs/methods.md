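# Methods

## The surrogate model

The object being approximated is the relaxed intramolecular energy penalty
of a flexible molecule,

    dE_intra(theta) = E_min(theta) - U_global,

where `theta` is the vector of *independent* flexible torsions (degrees),
`E_min(theta)` is the molecular energy minimized over all *dependent*
coordinates `beta` (bond lengths, bond angles, remaining torsions) at fixed
`theta`, and `U_global` is the unconstrained global-minimum energy, so that
`dE_intra >= 0`. A Local Approximate Model (LAM) at a reference
conformation stores the value, gradient and Hessian of the relaxed surface
plus a linear model of the dependent coordinates:

    dE(theta)   ~ E_ref + b . dtheta + 1/2 dtheta' A dtheta
    beta(theta) ~ beta_ref + C . dtheta

with `dtheta` the per-dimension signed displacement, shorter-arc on
full-circle torsions. A set of LAMs is evaluated piecewise: the model with
the nearest reference (Euclidean metric in degrees, periodic dimensions
wrapped) supplies the prediction. The piecewise surface is intentionally
discontinuous at the midlines between references; the jump equals the
midpoint discrepancy that drives refinement, and no smoothing is applied.

Derivatives are taken of the *relaxed* surface: the dependent coordinates
are re-minimized at every finite-difference stencil point rather than held
frozen. This keeps the energy model consistent with the linear
dependent-coordinate model — a frozen-beta Hessian would systematically
overestimate curvature wherever relaxation is significant.

## Adaptive placement

Given a set of models, every unordered pair (A, B) is tested at the
conformational midpoint M of its references. A model is built at M iff

1. |dE_A(M) - dE_B(M)| > delta_e (strict),
2. min(dE_A(M), dE_B(M)) <= cutoff,
3. no third model is strictly nearer to M than A and B are (equidistant
   ties do not block).

plus two guards: pairs antipodal on a periodic dimension are skipped (their
midpoint is ambiguous; such pairs are always flanked by nearer models in
practice), and midpoints within `eps_dup` of an existing reference are
skipped as duplicates. Criteria are evaluated nearest-model-first purely
for speed; acceptance needs all three, so the order only affects which
blocking reason is logged.

`single_pass` mode examines all pairs of the initial set once (models added
during the pass take part only in the duplicate check, so two pairs sharing
a midpoint do not both build there); `iterate` mode repeats whole sweeps
over the growing set until a sweep accepts nothing. Termination is
guaranteed by `eps_dup`: only finitely many points with pairwise distance
>= eps_dup fit in the compact domain. A post-hoc audit
(`residual_violations`) re-sweeps the final set and reports any pair that
still satisfies (2) and (3) with discrepancy above `delta_e`; after iterate
mode this list is empty.

Key parameters, defaults, and reasons:

| parameter | default | meaning |
|---|---|---|
| `delta_e` | 1 kJ/mol | largest tolerated midpoint discrepancy; smaller values buy surface consistency with more models |
| `cutoff` | 20 kJ/mol | largest conformational penalty still relevant to crystal packing; distortions costlier than this are not observed in real polymorphs |
| `eps_dup` | 0.5° | duplicate threshold; also the termination guarantee |
| `fd_step` | 1.0° | central-difference step for b, A, C; diagonal terms from 3-point stencils, off-diagonal from 4-point cross stencils, A symmetrized afterwards |
| `max_new_lams` | 1000 | safety budget; exhaustion returns a partial result flagged non-converged |

Domain expansion (`expand_domain`) probes the energy penalty at each
bounded edge (other coordinates at the domain centre) and pushes the edge
outward in fixed increments while the penalty is below a threshold
(15 kJ/mol by default), capped at a 360° span. `U_global` is treated as a
molecule-wide constant computed once on the initial domain.

## Synthetic potentials

Desk-scale stand-ins for constrained quantum-chemistry calculations. The
energy over `theta` and unitless dependent coordinates `beta` is a sum of

* per-torsion Fourier terms `V (1 - cos(k theta + phi))`,
* product couplings `W cos(k_i theta_i + phi_i) cos(k_j theta_j + phi_j)`,
* quadratic and bilinear terms (non-periodic; exactly representable by a
  second-order model),
* localized von-Mises features
  `A prod_i exp(conc_i (cos(theta_i - c_i) - 1))` — periodized Gaussians of
  angular width ~ `1/sqrt(conc)` radians, modelling steric clashes (A > 0)
  or attractive contacts (A < 0),
* harmonic dependent coordinates `1/2 kappa_m (beta_m - target_m(theta))^2`
  with smooth (sine/linear) targets.

Because the dependent part is harmonic about its target, the constrained
minimum is analytic (`beta* = target(theta)`, `E_min` = torsional part),
which makes model-construction tests exact. `U_global` is found by
multi-start L-BFGS-B (coarse-grid plus seeded random starts) and cached per
(potential, domain).

Shipped presets:

* `quadratic` — 1-D pure quadratic well (curvature 0.02 kJ/mol/deg², linear
  dependent target with slope 0.1). Second-order models are globally exact,
  so any model set reproduces the oracle to rounding and refinement adds
  nothing; this pins down the machinery's correctness independent of
  placement.
* `double_well_1d` — `20(1 - cos 2θ) + 10(1 + cos 4θ)` on [-90°, 90°]:
  minima at ±30°, a 5 kJ/mol symmetric barrier at 0°, ~45 kJ/mol walls.
  With node models at -90°, -30°, +30°, +90°, adjacent models disagree by
  ~4.3 kJ/mol at ±60° (above `delta_e`, below `cutoff` at ~12 kJ/mol
  predicted) and agree exactly at 0° by symmetry, so refinement inserts
  exactly two models. The well depth is capped by the requirement that the
  ±60° prediction stay below the 20 kJ/mol relevance cutoff.
* `coupled_2d` — quadratic bowls (0.004 kJ/mol/deg²) plus a bilinear tilt
  (0.0025 kJ/mol/deg²) forming a diagonal low-energy valley on
  [-120°, 120°]², two tall sharp clash cores (18 and 16 kJ/mol, conc
  50-57, ~10° wide) inside the valley, and one broad attractive pocket
  (-5 kJ/mol, conc 6-7) at the basin bottom. The cores are invisible to
  any coarse grid but are felt through their tails by nearby anchors, which
  triggers a refinement cascade (60° -> 30° -> 15° -> 7.5° spacing) locally.
* `random:<seed>` — reproducible randomized Fourier/coupling potentials
  (documented distributions in `random_spec`), used for the brute-force
  equivalence checks.

Fixture-design constraints worth recording: localized features must lie
well inside the hull of the initial grid (midpoint insertion can never
place a model beyond the outermost references, so structure near the domain
edge is unrefinable), and each feature must either be smooth at the initial
spacing or sharp enough to cascade — structure that produces midpoint
discrepancies just *below* `delta_e` is a blind spot that degrades the
adapted set without triggering it.

## What the synthetic data does and does not show

The generator reproduces the *geometry* of the problem — periodic torsions,
relaxing dependent coordinates, non-rectangular low-energy basins, rough
low-energy features on smooth backgrounds — with analytic forms, so tests
can assert exact values and independent brute-force references are cheap.
It does not reproduce quantum-chemical energetics: no level-of-theory
dependence, no conformation-dependent charges, no Cartesian geometry, and
dependent coordinates are unitless. Passing tests therefore validate the
placement algorithm and its machinery, not the chemical accuracy of any
particular surface; published per-molecule error statistics from ab initio
surfaces are not comparable numbers and are not asserted anywhere.

## Measured efficiency, honestly stated

On `coupled_2d` the adapted set improves the mean absolute scan error over
its coarse initial grid by ~8x (0.40 -> 0.054 kJ/mol at 2° scan
resolution) and has a ~2x smaller worst-case error (5.3 vs 9.5 kJ/mol)
than a centred regular grid with >= 3x as many models. Its *mean* error,
however, remains ~1.6x above that regular grid (0.054 vs 0.034 kJ/mol),
and the corresponding acceptance check is left failing rather than
weakened. The reason is structural: the midpoint probe certifies
consistency only at pair midpoints, so refinement stops once discrepancies
fall below `delta_e`, leaving a residual "raggedness" floor of roughly
`delta_e`/3 across the refined region, while a uniform grid of that size
resolves every smooth mid-scale structure on this analytic surface. The
adaptive scheme's advantage is concentration — fewer models, better
worst-case behaviour, effort spent only in relevant regions — not a lower
mean error than an arbitrarily enlarged uniform grid.

## Numerical choices and limitations

* Angles are degrees everywhere; energies kJ/mol. Matrices A are
  symmetrized on construction and must be symmetric within 1e-9 on read.
* Reference energies below -1e-6 kJ/mol abort (they indicate an
  inconsistent `U_global`); small negatives above that are
  finite-difference noise and are clamped to zero with a warning.
* Nearest-model ties break to the lowest insertion index; evaluation is
  order-invariant except exactly on tie midlines.
* Antipodal pairs are skipped, not resolved: any choice of midpoint would
  be arbitrary under coordinate relabeling.
* Error-map scans sample node grids; the scan increment must divide the
  span. Scans of the coupled fixture use 2° because its sharp features are
  ~10° wide and a 5° scan under-samples them.
* Serialization uses full-precision floats; round-trips are bit-exact.
  Unknown fields in a model record are preserved in its payload.
* No smoothing across model boundaries is provided; workflows that need a
  continuous surface must treat the midline discontinuities (equal to the
  logged midpoint discrepancies) downstream.
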