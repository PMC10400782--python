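# voidshape

Shape analysis of the solvent cavities that host dissolved molecules, and
linear models linking cavity shape to solvation thermodynamics.

When a solute sits in water it excludes solvent from a region — a cavity
whose geometry is set by how water packs around the solute's chemistry.
`voidshape` extracts that cavity from atomistic snapshots and reduces it to
eight shape descriptors: volume **V**, surface area **S**, the longest
surface geodesic **L**, the number of branches **nbr** (protrusions of the
surface reaching beyond 5 Å from the solute), and the branch-length
statistics **dmin, dmax, dave, dtotal**.  Standardized best-subset linear
models

> y = Σ_j w_j X_j,  R² = 1 − Σᵢ(yᵢ − ŷᵢ)² / Σᵢ(yᵢ − ȳ)²

with leave-one-out cross-validation (MSE_LOO, R²_LOO) then quantify how well
mean cavity shape predicts solvation free energies, enthalpies, entropies
and hydrophobicity scales — or, in reverse, how chemical properties (molar
mass, vdW volume, atom and ring counts, net charges) determine cavity shape.

The cavity is found by Voronoi analysis of the solvent sphere packing
(O/H vdW radii 1.52/1.2 Å): empty probe spheres of radius ≥ 1.2 Å at the
Voronoi vertices are merged wherever the bottleneck between them stays
above 1.1 Å, and the resulting void is surfaced by an alpha shape whose
graph yields the descriptors.  See `docs/methods.md` for the full model.

Intended users: researchers in solvation thermodynamics and molecular
simulation who have MD snapshots (GRO/PDB/XYZ) of a solute in water — or
who want a fully synthetic, analytically checkable test bed for cavity
methods.

## Worked example

A phantom cavity with known geometry, end to end:

```python
import numpy as np
from voidshape import (
    ExtractionParameters, make_phantom_frame, compute_probe_spheres,
    merge_probes, select_host_void, build_surface, detect_branches,
    summarize_descriptors,
)

# a 4-tendril star cavity (tendrils 8 A long) carved into a 3 nm water bath
frame, truth = make_phantom_frame("star", core_radius=4.0, n_tendrils=4,
                                  tendril_length=8.0, box_side=30.0, seed=14)

params = ExtractionParameters()          # probe 1.2 A, bottleneck 1.1 A
graph  = compute_probe_spheres(frame.without_solute(), params)
voids  = merge_probes(graph, params)
host   = select_host_void(voids, frame.solute_pos, frame.solute_radii, graph)
surf   = build_surface(host, graph)
br     = detect_branches(surf, frame.solute_pos, frame.solute_radii,
                         threshold=5.0, box=frame.box)
d      = summarize_descriptors(surf, br, frame.n_heavy())
print(f"V={d.V:.0f} A^3 (truth {truth.analytic_volume:.0f}+-{truth.volume_se:.0f})")
print(f"nbr={d.nbr} (truth {truth.true_branch_count}), dave={d.dave:.1f} A")
```

prints

```
V=677 A^3 (truth 646+-3)
nbr=4 (truth 4), dave=8.5 A
```

— the alpha-shape volume is within 5% of the Monte-Carlo union volume of
the carved region, all four tendrils are found, and the mean branch length
matches the 8 Å tendrils (measured from the solute surface, hence the
extra half-angstrom).

Fitting a target from descriptors (here a synthetic 20-row table):

```sh
voidshape fit table.csv --features V,S,L --target dG --out fit.json
# dG ~ L+V: R2=0.998 R2_LOO=0.997 MSE_LOO=0.002833 -> fit.json
```

The CLI also exposes `simulate` (synthetic bath), `phantom` (ground-truth
cavities), `extract` (voids as JSON), `describe` (per-frame descriptor CSV +
aggregate) and `aggregate`; run `voidshape --help`.

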