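"""Electrostatic potential mapped onto a density isosurface.

A charged Ca/Si/O platelet (here a small 800-atom slab; the generator
scales to tens of thousands of atoms) gets a promolecule density grid,
an isosurface of that density, a per-vertex ESP from the atomic point
charges, and an ascii PLY export with diverging blue-white-red colours
symmetric about 0.
"""

import numpy as np

import molforge as mf

platelet = mf.fixtures.make_platelet(800, seed=1)
print("atoms:", platelet.n_atoms,
      " net charge:", round(float(platelet.charges.sum()), 12))

rho = mf.promolecule_density(platelet, shape=(48, 48, 48))
surface = mf.isosurface(rho, 0.05 * rho.values.max())
print("isosurface:", surface.n_vertices, "vertices,",
      surface.n_triangles, "triangles")

colored, summary = mf.color_mesh_by_field(
    surface, (platelet.positions, platelet.charges)
)
v = colored.vertex_scalar
print("ESP range (hartree/e): %.4f .. %.4f" % (v.min(), v.max()))

mf.export_scene(colored, "platelet_esp.ply")
print("wrote platelet_esp.ply (per-vertex RGBA, red = positive potential)")
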