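"""File formats and the external converter plug-in mechanism.

Any XYZ file is a valid document in the native AXYZ dialect (the AXYZ
header IS an XYZ file); richer payloads (dipole, grids, orbitals,
objects) ride in XML sections after the header. Foreign formats go
through external converter commands registered by extension.
"""

import tempfile
from pathlib import Path

import numpy as np

import molforge as mf

tmp = Path(tempfile.mkdtemp())

# XYZ <-> AXYZ: the header of the dialect is plain XYZ
water = mf.fixtures.make_molecule("water")
water.metadata["dipole"] = np.array([0.0, 0.0, 1.85])  # Debye
doc = mf.Document(water)
mf.dipole_arrow(doc)                     # arrow object for the dipole
mf.write_axyz(doc, tmp / "water.axyz")
print((tmp / "water.axyz").read_text())

back = mf.read_axyz(tmp / "water.axyz")
print("objects restored:", len(back.objects),
      "dipole:", back.molecule.metadata["dipole"])

# a one-line registry entry turns any shell command into a converter
(tmp / "registry.yaml").write_text(
    'plugins:\n'
    '  - name: copy\n'
    '    command: "cp {in} {out}"\n'
    '    extensions: [".cpy"]\n'
    '    direction: import\n'
)
registry = mf.load_registry(tmp / "registry.yaml")
(tmp / "water.cpy").write_text((tmp / "water.axyz").read_text())
spec = mf.resolve_plugin(registry, tmp / "water.cpy")
imported = mf.convert_via_plugin(spec, tmp / "water.cpy")
print("imported via plug-in:", imported.molecule.formula())
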