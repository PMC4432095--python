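import numpy as np
import pytest

from molforge import (
    Atom,
    Document,
    GeomObject,
    Molecule,
    OrbitalRecord,
    ScalarGrid,
    convert_via_plugin,
    load_registry,
    read_axyz,
    read_cube,
    read_grid_cube,
    read_xyz,
    resolve_plugin,
    write_axyz,
    write_grid_cube,
    write_xyz,
)
from molforge.fields import Style
from molforge.fixtures import make_molecule


class TestXYZ:
    def test_round_trip_identity(self, benzene, tmp_path):
        p = tmp_path / "b.xyz"
        write_xyz(benzene, p)
        back = read_xyz(p)
        assert back.elements == benzene.elements
        assert np.abs(back.positions - benzene.positions).max() < 1e-6

    def test_write_read_write_byte_identical(self, water, tmp_path):
        p1, p2 = tmp_path / "a.xyz", tmp_path / "b.xyz"
        write_xyz(water, p1)
        write_xyz(read_xyz(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_three_frame_trajectory(self, water, tmp_path):
        pos = water.positions
        water.set_frames([pos, pos + 0.1, pos + 0.2])
        p = tmp_path / "t.xyz"
        write_xyz(water, p)
        back = read_xyz(p)
        assert back.n_frames == 3
        assert np.abs(back.frames[2] - pos - 0.2).max() < 1e-6

    def test_empty_molecule(self, tmp_path):
        p = tmp_path / "e.xyz"
        p.write_text("0\nempty\n")
        assert read_xyz(p).n_atoms == 0

    def test_charge_column(self, tmp_path):
        p = tmp_path / "q.xyz"
        p.write_text("1\n\nNa 0.0 0.0 0.0 1.0\n")
        mol = read_xyz(p)
        assert mol.atoms[0].charge == 1.0

    def test_bad_coordinate_reports_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\nt\nO 0 0 0\nH 0 zero 0\n")
        with pytest.raises(ValueError, match="line 4"):
            read_xyz(p)

    def test_count_mismatch(self, tmp_path):
        p = tmp_path / "short.xyz"
        p.write_text("5\nt\nO 0 0 0\n")
        with pytest.raises(ValueError):
            read_xyz(p)


def _payload_doc(rng):
    mol = make_molecule("water")
    mol.metadata["dipole"] = np.array([0.0, 0.0, 2.5])
    g = ScalarGrid((0, 0, 0), np.diag([0.5, 0.5, 0.5]),
                   rng.normal(size=(4, 4, 4)), "orb")
    doc = Document(mol, grids=[g])
    doc.orbitals.append(OrbitalRecord(0, "b1u", -0.51, 2.0, "ras2", g))
    doc.objects.append(GeomObject("arrow", [[0, 0, 0], [0, 0, 1]],
                                  Style((1, 0, 0), 1.0)))
    return doc


class TestAXYZ:
    def test_plain_xyz_is_valid_document(self, water, tmp_path):
        p = tmp_path / "w.xyz"
        write_xyz(water, p)
        doc = read_axyz(p)
        assert doc.molecule.n_atoms == 3
        assert doc.grids == [] and doc.objects == [] and doc.orbitals == []

    def test_header_is_valid_xyz(self, rng, tmp_path):
        doc = _payload_doc(rng)
        p = tmp_path / "d.axyz"
        write_axyz(doc, p)
        n = doc.molecule.n_atoms
        head = "\n".join(p.read_text().splitlines()[: 2 + n]) + "\n"
        q = tmp_path / "head.xyz"
        q.write_text(head)
        back = read_xyz(q)
        assert np.abs(back.positions - doc.molecule.positions).max() < 1e-6

    def test_full_round_trip(self, rng, tmp_path):
        doc = _payload_doc(rng)
        p = tmp_path / "d.axyz"
        write_axyz(doc, p)
        back = read_axyz(p)
        assert len(back.grids) == 1 and len(back.objects) == 1
        assert len(back.orbitals) == 1
        assert back.orbitals[0].grid is back.grids[0]
        assert back.orbitals[0].subspace == "ras2"
        assert np.abs(back.grids[0].values - doc.grids[0].values).max() < 1e-6
        assert np.allclose(back.molecule.metadata["dipole"], [0, 0, 2.5])
        assert back.objects[0].style.opacity == 1.0

    def test_serializer_deterministic_byte_identical(self, rng, tmp_path):
        doc = _payload_doc(rng)
        p1, p2 = tmp_path / "a.axyz", tmp_path / "b.axyz"
        write_axyz(doc, p1)
        write_axyz(read_axyz(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_unknown_section_preserved(self, tmp_path):
        p = tmp_path / "x.axyz"
        p.write_text(
            "1\nt\nHe 0.000000 0.000000 0.000000\n"
            '<axyz version="1.0">\n  <custom a="1">payload</custom>\n</axyz>\n'
        )
        doc = read_axyz(p)
        assert len(doc.extra) == 1
        q = tmp_path / "y.axyz"
        write_axyz(doc, q)
        assert "custom" in q.read_text() and "payload" in q.read_text()

    def test_malformed_xml_after_header(self, tmp_path):
        p = tmp_path / "bad.axyz"
        p.write_text("1\nt\nHe 0.0 0.0 0.0\n<axyz><grid></axyz>\n")
        with pytest.raises(ValueError, match="XML"):
            read_axyz(p)

    def test_xml_without_header_rejected(self, tmp_path):
        p = tmp_path / "nohdr.axyz"
        p.write_text("<axyz></axyz>\n")
        with pytest.raises(ValueError, match="header"):
            read_axyz(p)


class TestCube:
    def test_round_trip(self, rng, tmp_path):
        g = ScalarGrid((0.1, -0.2, 0.3), np.diag([0.5, 0.6, 0.7]),
                       rng.normal(size=(8, 8, 8)), "synthetic gaussian")
        p = tmp_path / "g.cube"
        write_grid_cube(g, p, mol=make_molecule("water"))
        g2, mol2 = read_cube(p)
        assert np.abs(g2.values - g.values).max() < 1e-10
        assert np.abs(g2.axes - g.axes).max() < 1e-6
        assert np.abs(g2.origin - g.origin).max() < 1e-6
        assert mol2.elements == ["O", "H", "H"]

    def test_bohr_angstrom_conversion(self, tmp_path):
        # one-bohr step in the file becomes 0.529177210903 angstrom
        p = tmp_path / "unit.cube"
        vals = "\n".join(["0.0 0.0 0.0 0.0"] * 2)  # 8 voxels for a 2x2x2 grid
        p.write_text(
            "t\nt\n 0 0.0 0.0 0.0\n 2 1.0 0.0 0.0\n 2 0.0 1.0 0.0\n"
            " 2 0.0 0.0 1.0\n" + vals + "\n"
        )
        g = read_grid_cube(p)
        assert g.axes[0, 0] == pytest.approx(0.529177210903, abs=1e-12)
        assert np.allclose(g.origin, 0.0)

    def test_voxel_count_mismatch(self, tmp_path):
        p = tmp_path / "bad.cube"
        p.write_text(
            "t\nt\n 0 0.0 0.0 0.0\n 2 1.0 0.0 0.0\n 2 0.0 1.0 0.0\n"
            " 2 0.0 0.0 1.0\n1.0 2.0 3.0\n"
        )
        with pytest.raises(ValueError, match="inconsistent"):
            read_grid_cube(p)


REGISTRY = """
plugins:
  - name: copyfmt
    command: "cp {in} {out}"
    extensions: [".cpy"]
    direction: import
  - name: pdb
    command: "cp {in} {out}"
    extensions: [".pdb", ".ent.pdb"]
    direction: import
"""


class TestPlugins:
    @pytest.fixture
    def registry(self, tmp_path):
        p = tmp_path / "reg.yaml"
        p.write_text(REGISTRY)
        return load_registry(p)

    def test_explicit_format_wins(self, registry):
        spec = resolve_plugin(registry, "file.weird", explicit_format="pdb")
        assert spec.format_name == "pdb"

    def test_longest_suffix_match(self, registry):
        assert resolve_plugin(registry, "a.pdb").format_name == "pdb"
        assert resolve_plugin(registry, "a.ent.pdb").format_name == "pdb"
        assert resolve_plugin(registry, "a.cpy").format_name == "copyfmt"

    def test_native_bypasses_plugins(self, registry):
        assert resolve_plugin(registry, "a.xyz") is None
        assert resolve_plugin(registry, "a.axyz") is None

    def test_unknown_extension_lists_known(self, registry):
        with pytest.raises(ValueError, match=r"\.cpy"):
            resolve_plugin(registry, "a.unknown")

    def test_resolution_is_pure(self, registry):
        a = resolve_plugin(registry, "x.pdb")
        b = resolve_plugin(registry, "x.pdb")
        assert a is b or a == b

    def test_identity_plugin_round_trip(self, registry, tmp_path, benzene):
        src = tmp_path / "b.axyz"
        write_axyz(Document(benzene), src)
        cpy = tmp_path / "b.cpy"
        cpy.write_text(src.read_text())
        doc = convert_via_plugin(resolve_plugin(registry, str(cpy)), cpy)
        direct = read_axyz(src)
        assert doc.molecule.elements == direct.molecule.elements
        assert np.abs(doc.molecule.positions - direct.molecule.positions).max() < 1e-9

    def test_script_emitting_fixed_molecule(self, tmp_path):
        text = "2\npair\nH 0.000000 0.000000 0.000000\nF 0.000000 0.000000 0.900000\n"
        script = tmp_path / "emit.sh"
        script.write_text(f"#!/bin/sh\ncat > /dev/null < $1\ncat << 'EOF' > $2\n{text}EOF\n")
        script.chmod(0o755)
        from molforge import PluginSpec

        spec = PluginSpec("fixed", f"sh {script} {{in}} {{out}}", (".fx",))
        (tmp_path / "in.fx").write_text("ignored")
        doc = convert_via_plugin(spec, tmp_path / "in.fx")
        assert doc.molecule.elements == ["H", "F"]

    def test_failing_converter_propagates_message(self, tmp_path):
        from molforge import PluginSpec

        spec = PluginSpec("bad", "sh -c {in}_{out}_missing", (".bad",))
        spec2 = PluginSpec(
            "bad2", f"sh {tmp_path / 'fail.sh'} {{in}} {{out}}", (".bad",)
        )
        (tmp_path / "fail.sh").write_text("#!/bin/sh\necho boom >&2\nexit 1\n")
        (tmp_path / "x.bad").write_text("x")
        with pytest.raises(RuntimeError, match="boom"):
            convert_via_plugin(spec2, tmp_path / "x.bad")

    def test_duplicate_extension_rejected(self, tmp_path):
        p = tmp_path / "dup.yaml"
        p.write_text(
            "plugins:\n"
            "  - {name: a, command: 'cp {in} {out}', extensions: ['.q']}\n"
            "  - {name: b, command: 'cp {in} {out}', extensions: ['.q']}\n"
        )
        with pytest.raises(ValueError, match="registered by both"):
            load_registry(p)
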