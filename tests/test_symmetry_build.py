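import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree

from molforge import (
    add_dummy,
    apply_replicate,
    axis_rotation_order,
    detect_point_group,
    make_operation,
    mark_group,
    select,
    symmetrize,
)
from molforge.fixtures import make_molecule
from tests.conftest import random_rigid_motion


def _benzene_minus_two_h():
    b = make_molecule("benzene")
    mol, _ = b.delete_atoms([6, 7])  # hydrogens on adjacent carbons 0, 1
    return mol


class TestMakeOperation:
    def test_inversion_about_dummy(self, benzene):
        mol = add_dummy(benzene, position=(1.0, 2.0, 3.0))
        op = make_operation(mol, select(mol, [mol.n_atoms - 1]), "inversion")
        assert np.allclose(op.matrix, -np.eye(3))
        assert np.allclose(op.apply([[1.0, 2.0, 3.0]]), [[1.0, 2.0, 3.0]])

    def test_c2_about_two_atoms(self, benzene):
        op = make_operation(benzene, select(benzene, [0, 3]), "rotation",
                            angle=180.0)
        assert np.linalg.det(op.matrix) == pytest.approx(1.0)
        # both pivots are fixed points
        for i in (0, 3):
            p = benzene.positions[i]
            assert np.allclose(op.apply(p[None]), p, atol=1e-12)

    def test_rotation_n_times_is_identity(self, benzene):
        for n in (2, 3, 4, 6):
            op = make_operation(benzene, select(benzene, [0, 3]), "rotation",
                                angle=360.0 / n)
            M = np.linalg.matrix_power(op.matrix, n)
            assert np.allclose(M, np.eye(3), atol=1e-9)

    def test_reflection_det_minus_one(self, water):
        op = make_operation(water, select(water, [0, 1, 2]), "reflection")
        assert np.linalg.det(op.matrix) == pytest.approx(-1.0)

    def test_collinear_reflection_rejected(self):
        from molforge import Atom, Molecule

        m = Molecule([Atom("C", (float(i), 0, 0)) for i in range(3)])
        with pytest.raises(ValueError, match="collinear"):
            make_operation(m, select(m, [0, 1, 2]), "reflection")

    def test_every_op_is_an_isometry(self, ethane, rng):
        pts = rng.normal(size=(8, 3)) * 3.0
        d0 = [np.linalg.norm(a - b) for a, b in itertools.combinations(pts, 2)]
        for op in (
            make_operation(ethane, select(ethane, [0]), "inversion"),
            make_operation(ethane, select(ethane, [0, 1]), "rotation", angle=73.0),
            make_operation(ethane, select(ethane, [2, 0, 1]), "reflection"),
            make_operation(ethane, select(ethane, [0, 1]), "translation"),
        ):
            img = op.apply(pts)
            d1 = [np.linalg.norm(a - b) for a, b in itertools.combinations(img, 2)]
            assert np.allclose(d0, d1, atol=1e-9)


class TestApplyReplicate:
    def test_naphthalene_from_benzene(self):
        mol = _benzene_minus_two_h()
        op = make_operation(mol, select(mol, [0, 1]), "rotation", angle=180.0)
        nap = apply_replicate(mol, op, None, 0.3)
        assert nap.n_atoms == 18
        assert nap.formula() == "C10H8"

    def test_inversion_route_matches_rotation_route(self):
        mol = _benzene_minus_two_h()
        rot = apply_replicate(
            mol, make_operation(mol, select(mol, [0, 1]), "rotation", angle=180.0),
            None, 0.3,
        )
        via = add_dummy(mol, midpoint_of=select(mol, [0, 1]))
        targets = mark_group(via, "explicit", ids=range(mol.n_atoms))
        inv = apply_replicate(
            via, make_operation(via, select(via, [via.n_atoms - 1]), "inversion"),
            targets, 0.3,
        )
        inv, _ = inv.delete_atoms([mol.n_atoms])  # drop the pivot dummy
        d, _ = cKDTree(rot.positions).query(inv.positions)
        assert d.max() < 1e-6

    def test_translation_doubles_isolated_tetrahedron(self):
        sio4 = make_molecule("sio4")
        mol = add_dummy(sio4, position=(0, 0, 0))
        mol = add_dummy(mol, position=(8.0, 0, 0))
        op = make_operation(mol, select(mol, [5, 6]), "translation")
        grp = mark_group(mol, "explicit", ids=range(5))
        out = apply_replicate(mol, op, grp, 0.3)
        assert out.n_atoms == 5 + 2 + 5

    def test_identity_merges_every_image(self, benzene):
        op = make_operation(benzene, select(benzene, [0, 3]), "rotation",
                            angle=360.0)
        out = apply_replicate(benzene, op, None, 0.3)
        assert out.n_atoms == benzene.n_atoms

    def test_cn_closure(self, water):
        # repeated C3 about an external axis closes onto <= 3x the set
        mol = add_dummy(water, position=(3.0, 0, 0))
        mol = add_dummy(mol, position=(3.0, 0, 1.0))
        n0 = mol.n_atoms
        op = make_operation(mol, select(mol, [3, 4]), "rotation", angle=120.0)
        for _ in range(3):
            mol = apply_replicate(mol, op, None, 0.1)
        assert mol.n_atoms <= 3 * n0
        # invariant under the operation: applying once more adds nothing
        again = apply_replicate(mol, op, None, 0.1)
        assert again.n_atoms == mol.n_atoms

    def test_element_clash_raises(self):
        from molforge import Atom, Molecule

        m = Molecule([Atom("C", (0, 0, 0)), Atom("N", (0.1, 0, 0))])
        op = make_operation(m, select(m, [0]), "inversion")
        with pytest.raises(ValueError, match="clash"):
            apply_replicate(m, op, mark_group(m, "explicit", ids=[1]), 0.3)


class TestSymmetrize:
    def test_planarize_displaced_benzene(self, benzene):
        benzene.atoms[0].position = benzene.atoms[0].position + [0, 0, 0.05]
        op = make_operation(benzene, select(benzene, [1, 2, 3]), "reflection")
        out, summary = symmetrize(benzene, op)
        assert np.abs(out.positions[:, 2]).max() < 1e-9
        assert summary["unmatched"] == []
        # invariant under the operation
        d, _ = cKDTree(out.positions).query(op.apply(out.positions))
        assert d.max() < 1e-9

    def test_symmetric_molecule_unchanged(self, benzene):
        op = make_operation(benzene, select(benzene, [0, 1, 2]), "reflection")
        out, _ = symmetrize(benzene, op)
        assert np.allclose(out.positions, benzene.positions, atol=1e-12)

    def test_idempotent(self, benzene):
        benzene.atoms[2].position = benzene.atoms[2].position + [0, 0.02, 0.04]
        op = make_operation(benzene, select(benzene, [0, 1, 3]), "reflection")
        once, _ = symmetrize(benzene, op)
        twice, _ = symmetrize(once, op)
        assert np.allclose(once.positions, twice.positions, atol=1e-12)

    def test_non_order2_rejected(self, benzene):
        op = make_operation(benzene, select(benzene, [0, 3]), "rotation",
                            angle=120.0)
        with pytest.raises(ValueError, match="order-2"):
            symmetrize(benzene, op)


class TestPointGroup:
    @pytest.mark.parametrize("name,symbol", [
        ("benzene", "D6h"),
        ("water", "C2v"),
        ("methane", "Td"),
        ("ethane", "D3d"),
        ("sio4", "Td"),
    ])
    def test_reference_molecules(self, name, symbol):
        mol = make_molecule(name)
        res = detect_point_group(mol)
        assert res.symbol == symbol
        # brute-force check: every reported element permutes the atoms
        _assert_elements_permute(mol, res)

    def test_invariant_under_rigid_motion(self, rng):
        for name in ("benzene", "water", "methane"):
            mol = make_molecule(name)
            ref = detect_point_group(mol).symbol
            for _ in range(3):
                R, t = random_rigid_motion(rng)
                moved = mol.copy()
                moved.set_positions(mol.positions @ R.T + t)
                assert detect_point_group(moved).symbol == ref

    def test_single_atom_is_kh(self):
        from molforge import Atom, Molecule

        assert detect_point_group(Molecule([Atom("Ar", (5, 5, 5))])).symbol == "Kh"

    def test_linear_molecules(self):
        from molforge import Atom, Molecule

        co2 = Molecule([Atom("O", (0, 0, -1.16)), Atom("C", (0, 0, 0)),
                        Atom("O", (0, 0, 1.16))])
        assert detect_point_group(co2).symbol == "Dinfh"
        hcn = Molecule([Atom("H", (0, 0, -1.07)), Atom("C", (0, 0, 0)),
                        Atom("N", (0, 0, 1.15))])
        assert detect_point_group(hcn).symbol == "Cinfv"

    def test_asymmetric_is_c1(self, rng):
        from molforge import Atom, Molecule

        m = Molecule([Atom(e, rng.normal(size=3) * 2)
                      for e in ("C", "N", "O", "F", "H")])
        assert detect_point_group(m).symbol == "C1"

    def test_axis_rotation_order_on_naphthalene(self):
        mol = _benzene_minus_two_h()
        op = make_operation(mol, select(mol, [0, 1]), "rotation", angle=180.0)
        nap = apply_replicate(mol, op, None, 0.3)
        axis = mol.positions[1] - mol.positions[0]
        assert axis_rotation_order(nap, mol.positions[0], axis) == 2


def _assert_elements_permute(mol, res, tol=0.1):
    from molforge.periodic import atomic_mass

    pos = mol.positions
    masses = np.array([atomic_mass(e) for e in mol.elements])
    com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
    pos = pos - com

    def check(M):
        new = pos @ M.T
        d, idx = cKDTree(pos).query(new)
        assert d.max() <= tol
        assert len(set(idx.tolist())) == len(pos)
        assert all(mol.elements[i] == mol.elements[j]
                   for i, j in enumerate(idx))

    from molforge.symmetry_build import _rotmat

    for order, axis in res.proper_axes:
        check(_rotmat(axis, 360.0 / order))
    for n in res.mirror_normals:
        check(np.eye(3) - 2.0 * np.outer(n, n))
    if res.has_inversion:
        check(-np.eye(3))
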