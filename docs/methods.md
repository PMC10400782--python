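# Methods

## The model

A solute dissolved in water carves out a cavity — a connected region of
space no solvent atom sphere reaches.  `voidshape` measures the *shape* of
that cavity and asks how much of solvation thermodynamics that shape alone
predicts.  The analysis has three stages.

### 1. Void extraction

The solute is removed from a snapshot and the remaining water is treated as
a packing of spheres: O with vdW radius 1.52 Å and H with 1.2 Å.  The box
is meshed by a Voronoi tessellation of the atom centers.  Each Voronoi
vertex is the center of a maximal empty sphere whose **empty radius** is its
distance to the nearest atom *surface*.  Vertices with empty radius at
least the **probe radius** (default 1.2 Å) become probe spheres.  Two
probes joined by a Voronoi edge are merged into the same void when the
narrowest empty radius along the edge — sampled at the two endpoints and
the midpoint — is at least the **bottleneck radius** (default 1.1 Å).
Voids are the connected components of this gated graph.  The **host void**
is the component whose probe-sphere union has the largest Monte-Carlo
overlap (20 000 samples, fixed internal seed) with the solute's vdW volume;
ties go to the smaller component id.

Two deliberate approximations:

* **Ordinary vs weighted Voronoi.**  The tessellation is the ordinary
  Voronoi diagram of atom centers; radii enter only through the empty
  radius.  The O/H radii differ by just 0.32 Å, so vertices sit close to
  the additively-weighted (true medial) positions.  The adequacy of this is
  enforced by an independent brute-force grid oracle (below), not assumed.
* **Three-point bottlenecks.**  The true minimum clearance along a Voronoi
  edge is bounded from above by sampling at three points.  Near the
  decision threshold this can merge or split marginal voids differently
  from the continuum; see *Limitations*.

Periodic boundaries are handled by replicating atoms within a 6 Å shell of
each face, tessellating, and keeping the vertices that wrap into the
primary cell; edges crossing the boundary are resolved by wrapping their
endpoints onto kept vertices.  Degenerate (co-spherical) inputs are broken
by a deterministic 1e-6 Å jitter keyed to atom index — applied to the
tessellation only, so probe emptiness is exact against the raw atoms.  Only
orthorhombic boxes are supported.

### 2. Shape descriptors

The void boundary is reconstructed as an alpha shape: points are sampled on
each probe sphere (deterministic Fibonacci lattice, ~1 point per 0.8 Ų),
points inside another probe are discarded, the interior of the union is
filled with a lattice at half the alpha radius (so the kept tetrahedra form
a solid whose boundary is one closed surface rather than a holed crust),
and Delaunay tetrahedra with circumradius at most `alpha = 2.0 x
probe_radius` are kept.  The boundary triangles of that complex, largest
closed component, outward-oriented, are the surface.  Probe centers are
unwrapped by a minimum-image BFS over the void's edges first; a void that
percolates the box has no consistent unwrapping and is rejected.

From the surface and its edge graph (mesh edges weighted by Euclidean
length):

| symbol | meaning | computation |
|---|---|---|
| V (ų) | volume | signed-tetrahedron sum over facets |
| S (Ų) | area | triangle-area sum |
| L (Å) | length | weighted graph diameter (all-pairs shortest paths) |
| nbr | branch count | density-peak clustering of high vertices |
| dmin/dmax/dave/dtotal (Å) | branch-length statistics | per cluster, max height |

plus the branch density `nbr / N^(2/3)` with N the solute heavy-atom count
(the surface of a compact solute grows like N^(2/3), so this compares
branchiness across solute sizes).

**Branches.**  Each surface vertex gets a height `h(v)` = distance to the
nearest solute vdW surface.  Vertices with `h > threshold` (default 5 Å)
are branch candidates.  Candidates are partitioned by density-peak
clustering: local density is a Gaussian kernel at bandwidth `dc =
threshold/2`; each point's separation δ is its distance to the nearest
denser point; cluster centers are the points above the largest gap in the
log of the sorted, max-normalised ρ·δ product (searched over the top 25
positions — branch counts are small, and the tail of the product sequence
carries only noise); every other candidate joins its nearest denser
neighbour's cluster.  A branch's length is the largest height among its
members.  A Gaussian kernel is used rather than an integer cutoff count
because uniform surface sampling makes integer densities tie in plateaus,
which breaks the nearest-denser-neighbour assignment; the continuous kernel
gives the same peaks with a strict ordering.

Raising the threshold removes candidates and can only prune or merge
protrusions, so `nbr` falls monotonically with the threshold and the
ranking of solutes by branchiness is threshold-stable — both are verified
on phantoms at 3/5/7 Å.

### 3. Regression

Per-solute mean descriptors (V, S, L, nbr, dmin, dmax, dave, dtotal) become
candidate features for standardized linear models `y = Σ_j w_j X_j`
predicting a thermodynamic or hydrophobicity target; a second mode predicts
each void descriptor from eight chemical properties (MM, vdW, #C, #Polar,
#Pos, #Neg, #5-ring, #6-ring).  Standardization is zero mean / unit SD
(population convention, `ddof` configurable), so no intercept is fit and
weights are unit-less and comparable.  Quality is `R² = 1 − SS_res/SS_tot`;
generalization is leave-one-out: the standardization and fit are redone on
each training fold (no leakage; a leaky global-standardization mode exists
behind a flag for comparison) and the held-out row is predicted on the
original scale, giving MSE_LOO (mean per-row squared error) and R²_LOO (the
R² formula applied to LOO predictions).  Subset selection enumerates all
2^p − 1 feature combinations (p ≤ 12) and minimizes MSE_LOO by default —
in-sample R² is monotone in subset size and cannot select; choosing it
explicitly triggers a warning.  Ties break toward fewer features, then
lexicographic order.  A leave-k-out diagnostic computes `(Error_i·√(N−i)) /
(Error_1·√(N−1))` for i = 2, 3; values near 1 confirm the expected 1/√N
error growth (if the fit is exact the ratio is 1 by convention).

## Synthetic data

No MD trajectories ship with the package; the generator produces geometric
stand-ins with known truth.

* **Water bath.**  Rigid 3-site waters (O–H 0.9572 Å, H–O–H 104.52°,
  random orientation) placed by random sequential insertion under a 2.6 Å
  minimum-image O–O hard core, at 33.4 molecules/nm³ by default (ambient
  density).  The achieved count must be within 5% of density x volume.
  Internal water geometry is irrelevant to cavity shape; only sphere
  positions matter.
* **Phantom cavities.**  A sphere (analytic V, S) or a star — a core
  sphere plus k capsule tendrils with pairwise angular separation ≥ 60°,
  tips reaching `core + tendril_length`; the union volume is Monte-Carlo
  integrated (10⁶ samples, standard error recorded).  Carving removes every
  water whose any atom sphere touches the region.  Because a
  random-insertion bath is much looser than equilibrated water, a bare
  carved cavity leaks into interstitial space (measured ~90% extra volume
  at r = 6 Å); `make_phantom_frame` therefore lines the carved wall with
  tangent, outward-oriented waters at 1.25 Å spacing — a geometric stand-in
  for the tight first hydration shell.  Wall spacing is intentionally far
  below the bath hard core: the wall is a boundary condition, not an
  equilibrium packing.  With the lining, sphere recovery is within ~1–3% of
  analytic for r ∈ {4, 6, 8} Å and stars recover nbr = k exactly for
  k = 2..5.
* **Regression fixtures.**  X columns are i.i.d. standard normal and
  `y = Xw + N(0, σ)`, so generating weights are already on the standardized
  scale up to noise.

What the bath does *not* emulate: hydrogen-bond network structure, the
first-peak O–O correlation of real water, and realistic bulk-void
statistics — the synthetic bath is qualitatively, not quantitatively,
water-like, so passing phantom tests certifies the geometry pipeline, not
agreement with MD-derived void distributions.

## The grid oracle

`grid_cavity_oracle` is an independent brute-force check: the atom-free
space is sampled on a grid (cell ≤ 0.5 Å), eroded to the probe-center
region (clearance ≥ probe radius) and re-dilated by the probe radius.  This
morphological opening equals the union of all empty probe spheres, so its
volume is directly comparable to the alpha-shape volume; components are
counted on the eroded set with 26-connectivity and periodic label merging.
`grid_component_volume` restricts to the single component containing a
point (the host cavity) before re-dilation.

## Numerical choices

* Alpha radius 2.0 x probe radius (2.4 Å): the smallest factor that kept
  phantom spheres watertight with margin at the chosen sampling density;
  recorded in run metadata and configurable.
* Branch length = max over cluster members of height `h(v)` — parameter-
  free, and reproduces tendril lengths on phantoms to ~0.5 Å.
* Surface sampling 0.8 Ų/point balances mesh fidelity (≤2% volume bias on
  spheres) against the all-pairs geodesic cost, which is quadratic in
  vertex count.
* Host-void ties and facet-group ties break toward the smaller id / lower
  atom index, deterministically.
* All random streams are `numpy` Generators seeded per call; nothing
  touches global state, and reruns are byte-identical.

## Problem sizes

Tests and the acceptance script run phantoms in 22–30 Å boxes (≈400–1000
waters), 10–20-row regression tables with up to 8 features, and 50-seed
replicates for the stochastic diagnostics — sizes at which every stage has
an analytic or exhaustive oracle and the full suite completes in a few
minutes on one core.

## Limitations

* Component counting near the probe threshold is approximate: marginal
  sub-probe pockets can fragment differently between the vertex graph and
  the continuum (the true clearance maxima sit at weighted-Voronoi
  vertices).  The tests assert the safe direction — the graph never merges
  what the continuum separates at the bottleneck level — plus volume
  agreement on phantoms; exact component-count equality with the grid is
  not claimed.
* Voids percolating the periodic box are rejected rather than surfaced.
* Only orthorhombic boxes; no triclinic cells, no trajectory formats that
  need binary decoders (export snapshots first).
* Experimental target tables (solvation free energies, hydrophobicity
  scales) are user-supplied; nothing in the package depends on them.
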