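# lamkit

Adaptive **Local Approximate Models** (LAMs) of intramolecular torsional
energy surfaces.

Crystal structure prediction (CSP) for flexible molecules needs the
intramolecular energy penalty ΔE<sub>intra</sub>(θ) — the cost of twisting a
molecule's flexible torsions θ away from its gas-phase minimum — at millions
of trial conformations during a global lattice-energy search. Evaluating it
ab initio each time is impossible, so the surface is replaced by a piecewise
surrogate: a set of *local models*, each a second-order Taylor expansion of
the relaxed energy about a reference conformation θ<sup>ref</sup>,

ΔE<sub>intra</sub>(θ) ≈ ΔE<sup>ref</sup> + **b**·Δθ + ½ Δθᵀ**A**Δθ,  β(θ) ≈ β<sup>ref</sup> + **C**·Δθ,

where Δθ is the (shorter-arc) displacement from the reference, **b** and
**A** are the gradient and Hessian of the relaxed surface, and **C** linearly
models the *dependent* coordinates β (bond lengths, angles, remaining
torsions) that relax as functions of θ. At a query point the model with the
nearest reference (Euclidean metric, periodic torsions wrapped) is used.

Placing models on a regular grid scales exponentially with the number of
flexible torsions. `lamkit` implements the *adaptive* alternative: examine
every pair of models (A, B), and insert a new model at their conformational
midpoint M only if

1. the two models' predictions at M differ by more than δ<sub>E</sub>
   (default 1 kJ/mol) — they are inconsistent there;
2. the lower of the two predictions is ≤ ΔE<sup>cutoff</sup> (default
   20 kJ/mol) — the region is low-energy enough to matter for CSP;
3. no third model is strictly nearer to M — otherwise neither A nor B would
   ever be consulted there.

Sweeps repeat until no pair triggers (or a single pass can be requested).
The quantum-chemistry caller is deliberately out of scope: the package ships
analytic synthetic potentials (with relaxing dependent coordinates) as desk-
scale oracles, and defines a minimal adapter protocol
(`lamkit.EnergyOracle`) for plugging in a real engine.

## Worked example

The single-torsion demo re-enacts adaptive refinement on a 1-D double-well
potential (minima at ±30°, symmetric barrier at 0°, steep walls at ±90°)
starting from four node models at −90°, −30°, +30°, +90°:

```console
$ lamkit demo benzoic
2 LAMs added at [-60.0, 60.0] deg; final count 6
```

Adjacent models disagree by ≈ 4.3 kJ/mol at ±60° (above the 1 kJ/mol
threshold), so two models are inserted there; at 0° the symmetric placement
makes the predictions agree exactly and no model is added. The regular-grid
alternative with the same coverage would need 7 models at ±15° spacing.

The 2-D demo runs the full pipeline — coarse 4×4 grid, iterate-mode
refinement, dense error scan — on a coupled two-torsion surface with a
tilted low-energy valley and sharp localized features:

```console
$ lamkit demo roy
initial 16 LAMs -> final 72 (56 added, 5 sweeps)
mean |error|: initial grid 0.392, adapted 0.051 kJ/mol
minimum LAM spacing: 5.3 deg
```

Refinement concentrates models around the two steric-clash cores (down to
5.3° spacing) and cuts the mean absolute scan error roughly eightfold while
leaving the smooth high-energy walls coarse.

Every step is also a composable command:

```bash
lamkit grid  --domain examples/double_well_1d.yaml \
             --oracle preset:double_well_1d --convention nodes --out ls.json
lamkit adapt --lamset ls.json --oracle preset:double_well_1d \
             --mode iterate --delta 1.0 --cutoff 20.0 \
             --out adapted.json --decisions decisions.csv
lamkit eval  --lamset adapted.json --theta 42
lamkit scan  --lamset adapted.json --oracle preset:double_well_1d \
             --increment 5 --out map.csv
lamkit report --map map.csv
```

Oracles are addressed as `preset:quadratic`, `preset:double_well_1d`,
`preset:coupled_2d`, `random:<seed>`, or a path to a potential-spec JSON
file. Exit codes: 0 success, 2 config/schema error, 3 numerical failure,
4 refinement budget exhausted.

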