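"""Edit a molecule in ad-hoc internal coordinates.

Selecting 2/3/4 atoms defines a transient distance/angle/torsion; the
first selected atom (or a marked group containing it) moves, everyone
else stays bit-exactly in place.
"""

import molforge as mf

ethane = mf.fixtures.make_molecule("ethane")

sel = mf.select(ethane, [2, 0, 1, 5])                    # H-C-C-H torsion
print("initial torsion (deg):", mf.measure(ethane, sel))  # -60 (staggered)

# rotate the whole CH3 group on carbon 0's side of the C-C bond
methyl = mf.mark_group(ethane, "side_of_bond", bond=(0, 1), side=0)
eclipsed = mf.set_internal(
    ethane, mf.InternalTarget(sel, 0.0, scope="group", group=methyl)
)
print("after group edit (deg):", mf.measure(eclipsed, sel))  # 0 (eclipsed)

# stretch the C-C bond; only atom 0 moves
stretched = mf.set_internal(
    eclipsed, mf.InternalTarget(mf.select(eclipsed, [0, 1]), 1.70)
)
print("C-C after stretch (A):",
      mf.measure(stretched, mf.select(stretched, [0, 1])))   # 1.70
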