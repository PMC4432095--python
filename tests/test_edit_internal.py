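import itertools

import numpy as np
import pytest

from molforge import (
    InternalTarget,
    add_dummy,
    attach_fragment,
    mark_group,
    measure,
    normal_mode_frames,
    select,
    set_cartesian,
    set_internal,
)
from molforge.fixtures import builtin_fragments, make_molecule


class TestMeasure:
    def test_benzene_cc_distance(self, benzene):
        assert measure(benzene, select(benzene, [0, 1])) == pytest.approx(1.39)

    def test_water_angle(self, water):
        assert measure(water, select(water, [1, 0, 2])) == pytest.approx(104.52)

    def test_coplanar_cis_dihedral_zero(self):
        from molforge import Atom, Molecule

        sq = Molecule([Atom("C", p) for p in
                       [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]])
        assert measure(sq, select(sq, [0, 1, 2, 3])) == pytest.approx(0.0, abs=1e-12)

    def test_staggered_ethane_dihedral(self, ethane):
        # analytic geometry: torsions of H pairs are +-60 or 180
        vals = sorted(
            round(abs(measure(ethane, select(ethane, [h1, 0, 1, h2]))), 6)
            for h1 in (2, 3, 4) for h2 in (5, 6, 7)
        )
        assert set(vals) == {60.0, 180.0}

    def test_dihedral_sign_convention(self):
        from molforge import Atom, Molecule

        m = Molecule([Atom("C", p) for p in
                      [(1, 0, 0), (0, 0, 0), (0, 0, 1), (0, 1, 1)]])
        assert measure(m, select(m, [0, 1, 2, 3])) == pytest.approx(90.0)

    def test_dihedral_matches_independent_oracle(self, rng):
        # cross-check sign and magnitude against MDAnalysis
        from MDAnalysis.lib.distances import calc_dihedrals
        from molforge import Atom, Molecule

        for _ in range(10):
            p = rng.normal(size=(4, 3)) * 2.0
            m = Molecule([Atom("C", row) for row in p])
            try:
                ours = measure(m, select(m, [0, 1, 2, 3]))
            except ValueError:
                continue
            ref = np.degrees(calc_dihedrals(p[0][None], p[1][None],
                                            p[2][None], p[3][None]))[0]
            assert ours == pytest.approx(ref, abs=1e-5)

    def test_collinear_torsion_undefined(self):
        from molforge import Atom, Molecule

        m = Molecule([Atom("C", (float(i), 0, 0)) for i in range(4)])
        with pytest.raises(ValueError, match="torsion"):
            measure(m, select(m, [0, 1, 2, 3]))


class TestSetInternal:
    def test_distance_moves_only_mover(self):
        h2 = make_molecule("h2", hh=0.74)
        sel = select(h2, [0, 1])
        out = set_internal(h2, InternalTarget(sel, 1.0))
        assert measure(out, sel) == pytest.approx(1.0, abs=1e-9)
        assert np.array_equal(out.positions[1], h2.positions[1])

    def test_group_torsion_rigid(self, ethane):
        grp = mark_group(ethane, "side_of_bond", bond=(0, 1), side=0)
        sel = select(ethane, [2, 0, 1, 5])
        start = measure(ethane, sel)
        out = set_internal(ethane, InternalTarget(sel, start + 120.0 - 360.0
                                                  if start + 120.0 > 180 else start + 120.0,
                                                  "group", grp))
        # all three H of the rotated CH3 moved together
        moved = [i for i in (2, 3, 4)
                 if not np.array_equal(out.positions[i], ethane.positions[i])]
        assert len(moved) == 3
        # internal distances of the moving group preserved
        ids = sorted(grp.members)
        for i, j in itertools.combinations(ids, 2):
            d0 = np.linalg.norm(ethane.positions[i] - ethane.positions[j])
            d1 = np.linalg.norm(out.positions[i] - out.positions[j])
            assert d1 == pytest.approx(d0, abs=1e-9)

    @pytest.mark.parametrize("ids,value", [
        ([0, 1], 1.6),            # distance
        ([0, 1, 2], 95.0),        # angle
        ([6, 0, 1, 7], 30.0),     # torsion
    ])
    def test_hits_target_and_freezes_others(self, benzene, ids, value):
        sel = select(benzene, ids)
        out = set_internal(benzene, InternalTarget(sel, value))
        assert measure(out, sel) == pytest.approx(value, abs=1e-9)
        untouched = [i for i in range(benzene.n_atoms) if i != ids[0]]
        assert np.array_equal(out.positions[untouched], benzene.positions[untouched])

    def test_identity_edit_is_noop(self, ethane):
        for ids in ([0, 1], [2, 0, 1], [2, 0, 1, 5]):
            sel = select(ethane, ids)
            out = set_internal(ethane, InternalTarget(sel, measure(ethane, sel)))
            assert np.allclose(out.positions, ethane.positions, atol=1e-12)

    def test_idempotent(self, ethane):
        sel = select(ethane, [2, 0, 1, 5])
        tgt = InternalTarget(sel, 25.0)
        once = set_internal(ethane, tgt)
        twice = set_internal(once, tgt)
        assert np.allclose(once.positions, twice.positions, atol=1e-12)

    def test_degenerate_angle_target_rejected(self, water):
        with pytest.raises(ValueError):
            InternalTarget(select(water, [1, 0, 2]), 180.0)


class TestCartesianAndDummies:
    def test_set_cartesian(self, water):
        out = set_cartesian(water, 0, (1.0, 2.0, 3.0))
        assert np.array_equal(out.positions[0], [1.0, 2.0, 3.0])
        assert np.array_equal(out.positions[1:], water.positions[1:])
        # overwrite with own position is the identity
        same = set_cartesian(water, 1, water.positions[1])
        assert np.array_equal(same.positions, water.positions)

    def test_moved_atom_distance_matches_closed_form(self, water):
        out = set_cartesian(water, 0, (0.0, 0.0, -1.0))
        d = measure(out, select(out, [0, 1]))
        assert d == pytest.approx(np.linalg.norm(out.positions[1] - [0, 0, -1.0]))

    def test_dummy_at_bond_midpoint(self, benzene):
        sel = select(benzene, [0, 1])
        out = add_dummy(benzene, midpoint_of=sel)
        mid = 0.5 * (benzene.positions[0] + benzene.positions[1])
        assert np.allclose(out.positions[-1], mid)
        assert out.atoms[-1].is_dummy

    def test_dummy_explicit(self, water):
        out = add_dummy(water, position=(1, 2, 3))
        assert np.array_equal(out.positions[-1], [1, 2, 3])


class TestAttachFragment:
    def test_methyl_gives_toluene(self, benzene):
        out = attach_fragment(benzene, 6, builtin_fragments()["methyl"])
        assert out.n_atoms == 15
        assert out.formula() == "C7H8"

    def test_h_for_h_is_congruent_with_matching_length(self, benzene):
        from scipy.spatial import cKDTree

        out = attach_fragment(benzene, 6, builtin_fragments()["hydrogen"],
                              bond_length=1.09)
        d, _ = cKDTree(benzene.positions).query(out.positions)
        assert d.max() < 1e-6

    def test_default_length_is_radii_sum(self, benzene):
        # C 0.76 + H 0.31 (Cordero)
        out = attach_fragment(benzene, 6, builtin_fragments()["hydrogen"])
        d = np.linalg.norm(out.positions[-1] - out.positions[0])
        assert d == pytest.approx(1.07)

    def test_durene_by_four_methyls(self):
        mol = make_molecule("durene")
        assert mol.n_atoms == 24
        assert mol.formula() == "C10H14"

    def test_non_hydrogen_site_rejected(self, benzene):
        with pytest.raises(ValueError, match="hydrogen"):
            attach_fragment(benzene, 0, builtin_fragments()["methyl"])


class TestNormalModes:
    def test_zero_amplitude_frames_identical(self, water, rng):
        mode = rng.normal(size=(3, 3))
        out = normal_mode_frames(water, mode, 0.0, 6)
        for f in out.frames:
            assert np.array_equal(f, water.positions)

    def test_quarter_period_hits_full_amplitude(self, water, rng):
        mode = rng.normal(size=(3, 3))
        out = normal_mode_frames(water, mode, 0.3, 4)
        assert np.allclose(out.frames[1], water.positions + 0.3 * mode, atol=1e-12)
        assert np.array_equal(out.frames[0], water.positions)

    def test_symmetric_stretch_keeps_oh_equal(self, water):
        u1 = water.positions[1] - water.positions[0]
        u2 = water.positions[2] - water.positions[0]
        mode = np.vstack([np.zeros(3), u1 / np.linalg.norm(u1),
                          u2 / np.linalg.norm(u2)])
        out = normal_mode_frames(water, mode, 0.1, 8)
        for f in out.frames:
            d1 = np.linalg.norm(f[1] - f[0])
            d2 = np.linalg.norm(f[2] - f[0])
            assert d1 == pytest.approx(d2, abs=1e-12)

    def test_mismatched_mode_rejected(self, water):
        with pytest.raises(ValueError):
            normal_mode_frames(water, np.zeros((2, 3)), 0.1, 4)
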