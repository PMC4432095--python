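# molforge

Headless molecular building, editing and analysis for computational
chemists: everything an interactive molecular editor does *between*
mouse clicks — selection-driven geometry edits in ad-hoc internal
coordinates, symmetry operations as building tools, point-group
detection, orbital isosurfaces with electrostatic-potential colouring,
and restricted-active-space (RAS) bookkeeping — exposed as a Python
library plus a thin CLI, so that multi-step constructions are
scriptable and reproducible instead of interactive.

## What it computes

**Ad-hoc internal coordinates.** An ordered selection of 2/3/4 atoms
defines a transient bond length *r*, valence angle *θ* or dihedral
*φ(A–B–C–D)* (IUPAC sign: `atan2((n₁×n₂)·û_BC, n₁·n₂)` with
n₁ = b₁×b₂, n₂ = b₂×b₃). Setting a coordinate moves the
first-selected atom — or a marked group containing it, rigidly —
along the line, about the in-plane normal at the vertex, or about the
B–C axis; every other atom is untouched bit-exactly and the re-measured
value lands within 10⁻⁹ of the target.

**Symmetry as a building tool.** One pivot → inversion; two pivots →
rotation (or translation); three pivots → reflection. `apply_replicate`
copies atoms through the operation and merges images that land within a
threshold (default 0.3 Å) of an existing atom into the averaged
position — so benzene minus two adjacent H plus a C₂ about the bare
C–C bond *is* naphthalene. `symmetrize` uses the same pairing to make a
distorted structure exactly invariant under an order-2 operation.
`detect_point_group` assigns a Schoenflies symbol (C₁ … D₆ₕ, Td, Kₕ)
by explicit element search over candidate axes and planes.

**Scalar fields.** Marching-cubes isosurfaces (signed pairs for orbital
lobes), pointwise grid arithmetic (spin densities as α−β), densities
ρ = Σᵢ nᵢψᵢ², the point-charge electrostatic potential
V(r) = Σᵢ qᵢ/|r−rᵢ| in atomic units (chunked for large systems), and
σ/π classification of orbitals by reflection parity through the
molecular plane — the basis for picking an aromatic active space and
exporting it as a RAS input block.

**Formats.** XYZ (multi-frame trajectories), a native annotated-XYZ
dialect (`.axyz`: the first 2+n lines are a plain XYZ file; dipoles,
grids, orbitals, annotation objects and the saved view ride in XML
sections after it), Gaussian cube grids (bohr at the boundary), ascii
PLY scenes with per-vertex diverging colours, and foreign formats via
external converter plug-ins registered by extension in a YAML config.

## Worked example

```python
import molforge as mf

benzene = mf.fixtures.make_molecule("benzene")
frag, _ = benzene.delete_atoms([6, 7])     # strip two adjacent hydrogens
c2 = mf.make_operation(frag, mf.select(frag, [0, 1]), "rotation", angle=180.0)
naphthalene = mf.apply_replicate(frag, c2, merge_threshold=0.3)
print(naphthalene.n_atoms, naphthalene.formula(),
      mf.detect_point_group(naphthalene).symbol)
```

prints

```
18 C10H8 D2h
```

— the two on-axis carbons merged with their own images, the other
eight atoms replicated, and the result is naphthalene with the correct
point group. `examples/` holds one short narrative script per
capability (symmetry building, internal-coordinate editing, point
groups, active-space selection, ESP surfaces, formats/plug-ins,
droplet dipoles); each prints the numbers it computes.

## Command line

```
molforge pointgroup benzene.xyz            # -> D6h
molforge convert in.xyz out.axyz
molforge build in.xyz script.edit out.xyz
molforge isosurface grid.cube out.ply --isovalue 0.05 --esp
molforge fixtures platelet slab.axyz --n 2000
```

Edit scripts replace the interactive workflow; grammar (one operation
per line, `#` starts a comment):

```
script    = { line } ;
line      = [ op ] [ "#" comment ] newline ;
op        = "select" id { id }                 (* 1-4 atoms: focus *)
          | "set" value | "setg" value         (* atom / marked-group scope *)
          | "delete" id { id }
          | "cart" id x y z
          | "dummy" ( x y z | "mid" id { id } )
          | "mark" ( "element" symbol | "ids" id { id }
                   | "bonded" id | "side" id id id )
          | "unmark"
          | "attach" fragment id
          | "rotate" angle [ "merge" thr ]
          | "reflect" [ "merge" thr ]
          | "invert" [ "merge" thr ]
          | "translate" [ "multiple" k ] [ "merge" thr ] ;
```

Replication operations act on the marked group if one is set, else on
all atoms, using the current selection's atoms as pivots.

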