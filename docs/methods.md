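# Methods

This note records the models, conventions and numerical choices behind
molforge, and what the synthetic test inputs do and do not demonstrate.

## Molecular model and bond perception

Molecules are ordered atom lists (element symbol or the dummy token
`"X"`, Cartesian position in Å, optional point charge) with ids equal
to the 0-based list position; deletions compact ids and return an
old→new map so callers can re-anchor selections. Dummy atoms are pure
geometric pivots: massless, never bonded, excluded from bond
perception, density and point-group analysis.

Bonds are a display/grouping heuristic, not a bond-order model: atoms
i, j are bonded iff |rᵢ−rⱼ| ≤ s·(Rᵢ+Rⱼ) with Cordero (2008)
single-bond covalent radii and scale s = 1.2. The scale is exposed
because 1.2 is a convention, not physics; the perception is
rotation/translation invariant by construction (distances only) and
runs on a k-d tree so large slabs stay O(n log n).

## Internal-coordinate edits

A selection of 2/3/4 atoms defines the coordinate; the first selected
atom is the mover. Dihedrals use the IUPAC sign convention written as
`atan2((n₁×n₂)·û_BC, n₁·n₂)`; the implementation is cross-checked in
the tests against MDAnalysis on random geometries. Rotational edits
build the Rodrigues matrix for the signed delta; because the sign of
the rotation sense depends on the axis orientation, the implementation
evaluates both senses and keeps the one whose re-measured value hits
the target (exact to ~1e-12; the acceptance bound is 1e-9). Group
edits move the marked group as a rigid body; fixed reference atoms may
sit in the group only when the edit leaves them in place anyway (the
angle vertex and the torsion's two axis atoms) — this makes the
natural "one side of the bond" group usable directly for torsions.
Angle targets of exactly 0° or 180° are rejected: the rotation plane
is undefined there.

Fragment attachment replaces a hydrogen (it must have exactly one
bond) by a fragment whose metadata names its link atom and an optional
roll-reference atom. The open-valence direction of the fragment is
−Σ û(link→neighbour); the new bond length defaults to the sum of
covalent radii, with an explicit `bond_length` override for callers
that want to preserve a specific geometry (e.g. re-attaching H at an
aromatic 1.09 Å rather than the 1.07 Å radii sum). The residual roll
angle is fixed deterministically by placing the reference atom
anti-periplanar to the lowest-id heavy neighbour of the attachment
atom. Whether an editor should move the lone atom or its bonded
subtree by default is genuinely open; molforge moves the atom alone
and makes group motion an explicit scope.

## Symmetry operations, merging and symmetrization

Operations are affine isometries x → Mx + t assembled from pivot
points: inversion (M = −I about the pivot), rotation (Rodrigues about
the two-pivot axis), reflection (householder through the three-pivot
plane), translation (integer multiples of the pivot difference).
Replication appends images of the target atoms; images within the
merge threshold (default 0.3 Å — a documented choice, exposed as a
parameter) of an existing atom merge greedily nearest-first (ties by
lower id), the survivor taking the pairwise average position. Merging
different elements raises a "symmetry clash"; dummies merge only with
dummies. Symmetrization accepts order-2 operations only (inversion,
reflection, C₂) and moves each matched atom to the average of itself
and its partner's image, which makes the set exactly invariant and the
operation idempotent; unmatched atoms are reported, not moved.

## Point-group detection

The molecule is centred on its mass-weighted centroid. Candidate
proper axes come from the inertia eigenvectors, atom position vectors
and same-element pair midpoints/cross products (pairs capped at 60
atoms to bound the O(n²) candidate set); mirror-normal candidates add
same-element difference vectors. An element is accepted iff it maps
the labelled atom set onto itself within the tolerance (default
0.1 Å), verified as a bijection via nearest-neighbour matching per
element. The Schoenflies symbol follows the conventional tree: single
atom → Kₕ; collinear → C∞v/D∞ₕ; two or more C₃⁺ axes → icosahedral /
octahedral / tetrahedral families split by C₅/C₄ counts, mirrors and
inversion; otherwise the principal-axis tree (Dnh/Dnd/Dn, Cnh/Cnv/S₂n/Cn,
falling back to Cs/Ci/C₁). Rotation orders are searched up to 8 by
default (configurable); translations are never considered — point
groups only. The detector is invariant under rigid motion because all
candidates are derived from the centred geometry itself.

## Scalar fields

Grids store C-ordered values (last axis fastest) on a possibly
non-orthogonal lattice; cube I/O converts bohr↔Å at the boundary with
1 bohr = 0.529177210903 Å. Isosurfaces use marching cubes with the
classic 15-case table, run in index space and mapped through the
lattice; degenerate (zero-area) triangles are dropped. On the smooth
fields this package targets the classic table produces closed surfaces
(the |r| sphere test checks Euler characteristic 2 and vertex radii
within one voxel diagonal); fields with checkerboard-ambiguous faces
could produce topological artifacts, which is an accepted limitation.

ESP is V(r) = Σ qᵢ/|r−rᵢ| in hartree/e with positions converted to
bohr; evaluation is chunked (default 2048 points) so the distance
matrix stays bounded in memory, and the result is independent of chunk
size to the last bit because each point's sum is computed identically.

σ/π classification samples 500 seeded point pairs (p, mirror p),
discards samples below the noise floor 10⁻⁶·max|ψ|, votes each pair
symmetric or antisymmetric by comparing |ψ(p)∓ψ(mirror p)|, and
requires a 95 % majority; anything less is "mixed". The promolecule
density used for surface construction is Σ Z·exp(−r/0.5 Å) per atom
with a 4 Å cutoff filled locally per atom — adequate for a molecular
envelope, with no pretence of being a real electron density.

## Orbital spaces

Records carry irrep label, energy (hartree), occupation ∈ [0,2] and a
subspace tag from {frozen, inactive, ras1, ras2, ras3, secondary,
deleted}. Filtering is a conjunction of criteria preserving order and
hiding hidden records by default; "orbital type" means the σ/π/mixed
parity classification above, since no finer definition is standard.
The RAS export emits per-subspace per-irrep counts plus a type-index
string (one letter per orbital: f,i,1,2,3,s,d in index order). The
dialect is versioned and modelled on common RAS input conventions;
byte compatibility with any specific quantum-chemistry code is not
claimed — converter plug-ins own that boundary.

## File formats and plug-ins

The native dialect keeps the XYZ header (so any XYZ-aware tool can
read the geometry, and any XYZ file is a valid document with empty
sections) and puts payloads in XML sections under a versioned root.
Coordinates serialize as `%.6f`, grid values as `%.10e`, which makes
write∘read∘write byte-identical; unknown XML sections are carried
through round-trips verbatim. Plug-ins are external commands with
`{in}`/`{out}` placeholders registered by extension in YAML;
resolution is a pure function (explicit format > longest suffix >
native bypass), communication is via files, and failures propagate the
converter's stderr.

## Synthetic data

The fixture generators define the test conditions: idealised
geometries (benzene C–C 1.39 Å / C–H 1.09 Å, water 0.9572 Å / 104.52°,
staggered ethane, Si–O 1.62 Å); a charge-balanced CaSiO₃-like slab
motif replicated by translations to an exact atom count (9360 for the
scale demonstration), with seeded element-dependent charges
(Ca +1.5±0.2, Si +1.8±0.2, O −1.1±0.2) shifted to exactly zero net
charge; Gaussian s/p atomic orbitals combined with benzene-ring
Hückel-like coefficients on a shared ≤0.35 Å lattice (6 pz
combinations odd through the plane, 12 even ones); and droplet
snapshots with ≥2.5 Å centre separation and 1.85 D unit-random
dipoles. All randomness flows through one seeded generator per call —
same inputs, bit-identical outputs.

These stand-ins exercise the geometry, bookkeeping and field
machinery, not the physics: passing tests show the algorithms are
correct on clean inputs, and say nothing about basis-set quality,
real charge distributions, or orbitals of correlated wavefunctions.
Problem sizes in the test suite (64³ grids, 9360 atoms, 18 orbitals on
~40³ lattices) were chosen as the smallest sizes that still exercise
the chunked/local-fill code paths.

## Known limitations

- No bond orders, aromaticity or force-field typing; bonds are purely
  geometric.
- Geometry optimisation is delegated to compute-direction plug-ins;
  no optimizer is built in.
- Space groups are out of scope: translations build periodic motifs
  but are never classified.
- Maximum searched rotation order defaults to 8; genuine C₉⁺ principal
  axes would be under-reported unless the cap is raised.
- Computing orbitals from basis sets is out of scope; grids are
  inputs.
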