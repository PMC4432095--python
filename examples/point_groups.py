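"""Detect Schoenflies point groups of reference molecules.

The detector centres each molecule on its mass-weighted centroid,
searches candidate axes/planes and accepts an element when it permutes
the labelled atom set within the tolerance (default 0.1 A).
"""

import molforge as mf

for name in ("benzene", "water", "methane", "ethane", "sio4", "durene"):
    mol = mf.fixtures.make_molecule(name)
    res = mf.detect_point_group(mol)
    print(f"{name:8s} -> {res.symbol:5s} "
          f"(principal axis order {res.order_principal}, "
          f"{len(res.mirror_normals)} mirror planes, "
          f"inversion={res.has_inversion})")
# benzene D6h, water C2v, methane/SiO4 Td, staggered ethane D3d
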