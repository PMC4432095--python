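"""Editing in ad-hoc internal coordinates.

A transient internal coordinate is defined by an ordered atom
selection: two atoms give a distance, three a valence angle (at the
middle atom), four a signed dihedral A-B-C-D. The first selected atom
is the mover; an edit moves it alone or, with group scope, moves a
marked group rigidly. All other atoms keep their exact positions.

Dihedral sign convention: with b1 = B-A, b2 = C-B, b3 = D-C and the
plane normals n1 = b1 x b2, n2 = b2 x b3, the dihedral is
``atan2((n1 x n2) . u_bc, n1 . n2)`` in (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .mol_model import Atom, Group, Molecule, Selection, perceive_bonds, select
from .periodic import DUMMY, covalent_radius

__all__ = [
    "InternalTarget",
    "measure",
    "set_internal",
    "set_cartesian",
    "add_dummy",
    "attach_fragment",
    "normal_mode_frames",
]


@dataclass(frozen=True)
class InternalTarget:
    selection: Selection
    value: float                      # angstrom or degrees
    scope: Literal["atom", "group"] = "atom"
    group: Group | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("target value must be finite")
        if self.selection.focus == "angle" and not (0.0 < self.value < 180.0):
            raise ValueError("angle target must lie strictly in (0, 180) degrees")
        if self.scope == "group":
            if self.group is None:
                raise ValueError("group scope needs a group")
            if self.selection.mover not in self.group.members:
                raise ValueError("group must contain the first-selected atom")


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"degenerate {what}: coincident points")
    return v / n


def measure(mol: Molecule, selection: Selection) -> float:
    """Distance (angstrom), angle or signed dihedral (degrees)."""
    p = [mol.atoms[i].position for i in selection.ordered]
    if selection.focus == "distance":
        return float(np.linalg.norm(p[0] - p[1]))
    if selection.focus == "angle":
        u = _unit(p[0] - p[1])
        v = _unit(p[2] - p[1])
        return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))
    if selection.focus == "torsion":
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
            raise ValueError("undefined torsion: collinear atoms")
        u_bc = _unit(b2)
        ang = math.degrees(
            math.atan2(float(np.cross(n1, n2) @ u_bc), float(n1 @ n2))
        )
        return 180.0 if ang <= -180.0 else ang
    raise ValueError("measure needs a 2-, 3- or 4-atom selection")


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    u = _unit(axis, "rotation axis")
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def _moving_set(mol: Molecule, target: InternalTarget) -> list[int]:
    sel = target.selection
    if target.scope == "atom":
        return [sel.mover]
    movers = set(target.group.members)  # type: ignore[union-attr]
    # fixed references may sit in the group only if the edit leaves them
    # in place anyway: the angle vertex and the torsion's axis atoms
    if sel.focus == "distance":
        immobile: set[int] = set()
    elif sel.focus == "angle":
        immobile = {sel.ordered[1]}
    else:
        immobile = {sel.ordered[1], sel.ordered[2]}
    offending = (movers - immobile) & set(sel.ordered[1:])
    if offending:
        raise ValueError(
            f"mover group contains a fixed reference atom: {sorted(offending)}"
        )
    return sorted(movers - immobile)


def set_internal(mol: Molecule, target: InternalTarget) -> Molecule:
    """Set a distance/angle/torsion by moving the first-selected atom
    (or its group, rigidly); everything else is untouched bit-exactly."""
    sel = target.selection
    current = measure(mol, sel)
    movers = _moving_set(mol, target)
    out = mol.copy()
    pos = out.positions
    p = [pos[i] for i in sel.ordered]

    if sel.focus == "distance":
        if target.value <= 0:
            raise ValueError("distance target must be positive")
        u = _unit(p[0] - p[1])
        shift = (target.value - current) * u
        for i in movers:
            pos[i] = pos[i] + shift
    elif sel.focus in ("angle", "torsion"):
        if sel.focus == "angle":
            axis = np.cross(p[0] - p[1], p[2] - p[1])
            if np.linalg.norm(axis) < 1e-10:
                raise ValueError("undefined angle plane: collinear selection")
            pivot = p[1]
        else:
            axis = p[2] - p[1]
            pivot = p[1]
        delta = target.value - current
        # rotation sense depends on the axis orientation; pick the sign
        # that lands the re-measured coordinate on the target
        for sign in (1.0, -1.0):
            R = _rotation_matrix(axis, sign * delta)
            trial = pos.copy()
            for i in movers:
                trial[i] = pivot + R @ (pos[i] - pivot)
            out.set_positions(trial)
            got = measure(out, sel)
            err = abs(got - target.value)
            if sel.focus == "torsion":
                err = min(err, abs(err - 360.0))
            if err < 1e-7:
                pos = trial
                break
        else:
            raise ValueError("edit failed to reach the target value")
    else:
        raise ValueError("set_internal needs a 2-, 3- or 4-atom selection")

    out.set_positions(pos)
    return out


def set_cartesian(mol: Molecule, atom_id: int, position: Sequence[float]) -> Molecule:
    """Directly overwrite one atom's Cartesian position."""
    mol._check_id(atom_id)
    out = mol.copy()
    out.atoms[atom_id].position = np.asarray(position, dtype=float).reshape(3)
    if out.frames is not None:
        out.frames[0][atom_id] = out.atoms[atom_id].position
    return out


def add_dummy(
    mol: Molecule,
    position: Sequence[float] | None = None,
    midpoint_of: Selection | None = None,
) -> Molecule:
    """Append a dummy pivot atom, explicitly placed or at the arithmetic
    mean of a selection's atoms (e.g. a bond midpoint)."""
    if (position is None) == (midpoint_of is None):
        raise ValueError("give exactly one of position / midpoint_of")
    if midpoint_of is not None:
        pts = np.array([mol.atoms[i].position for i in midpoint_of.ordered])
        position = pts.mean(axis=0)
    out = mol.copy()
    out.add_atom(Atom(DUMMY, np.asarray(position, dtype=float)))
    return out


def _attachment_direction(fragment: Molecule, link: int, bonds) -> np.ndarray | None:
    """Open-valence direction at the link atom: minus the sum of unit
    vectors to its bonded neighbours; None if the link atom is isolated."""
    neigh = [b.b if b.a == link else b.a for b in bonds if link in (b.a, b.b)]
    if not neigh:
        return None
    s = np.zeros(3)
    for j in neigh:
        s += _unit(fragment.atoms[j].position - fragment.atoms[link].position)
    if np.linalg.norm(s) < 1e-8:
        return None
    return -_unit(s)


def attach_fragment(
    mol: Molecule,
    site: int,
    fragment: Molecule,
    bond_length: float | None = None,
    bond_scale: float = 1.2,
) -> Molecule:
    """Replace a hydrogen atom by a molecular fragment.

    ``site`` must be a hydrogen bonded to exactly one heavy atom. The
    fragment's metadata declares ``link_atom`` (the atom that bonds to
    the heavy atom) and optionally ``ref_atom`` (fixes the roll angle:
    it is placed anti-periplanar to the lowest-id heavy neighbour of
    the attachment atom). The new bond length defaults to the sum of
    covalent radii and can be overridden with ``bond_length``.
    """
    mol._check_id(site)
    if mol.atoms[site].element != "H":
        raise ValueError(f"attachment site {site} is not a hydrogen atom")
    bonds = perceive_bonds(mol, bond_scale)
    neigh = [b.b if b.a == site else b.a for b in bonds if site in (b.a, b.b)]
    if len(neigh) != 1:
        raise ValueError(
            f"attachment site must have exactly one bond, found {len(neigh)}"
        )
    heavy = neigh[0]
    if "link_atom" not in fragment.metadata:
        raise ValueError("fragment metadata must declare link_atom")
    link = int(fragment.metadata["link_atom"])
    ref = fragment.metadata.get("ref_atom")

    d = _unit(mol.atoms[site].position - mol.atoms[heavy].position)
    if bond_length is None:
        bond_length = covalent_radius(mol.atoms[heavy].element) + covalent_radius(
            fragment.atoms[link].element
        )

    frag = fragment.copy()
    fbonds = perceive_bonds(frag, bond_scale)
    fdir = _attachment_direction(frag, link, fbonds)
    fpos = frag.positions - frag.atoms[link].position
    if fdir is not None:
        # rotate the fragment so its open valence points back along -d
        R = _align_rotation(fdir, -d)
        fpos = fpos @ R.T
    fpos = fpos + mol.atoms[heavy].position + bond_length * d

    out, mapping = mol.delete_atoms([site])
    offset = out.n_atoms
    for a, p in zip(frag.atoms, fpos):
        out.add_atom(Atom(a.element, p, a.charge))

    # deterministic roll: put ref_atom anti-periplanar to the lowest-id
    # heavy neighbour of the attachment atom (if both exist)
    heavy_new = mapping[heavy]
    if ref is not None and fdir is not None:
        ref_new = offset + int(ref)
        link_new = offset + link
        nbonds = perceive_bonds(out, bond_scale)
        hn = sorted(
            (b.b if b.a == heavy_new else b.a)
            for b in nbonds
            if heavy_new in (b.a, b.b)
            and (b.b if b.a == heavy_new else b.a) != link_new
            and out.atoms[b.b if b.a == heavy_new else b.a].element != "H"
        )
        if hn:
            from .mol_model import mark_group

            sel = select(out, [ref_new, link_new, heavy_new, hn[0]])
            try:
                frag_ids = frozenset(range(offset, out.n_atoms))
                tgt = InternalTarget(sel, 180.0, scope="group",
                                     group=Group(frag_ids))
                out = set_internal(out, tgt)
            except ValueError:
                pass  # collinear reference geometry: roll is immaterial
    out.bonds = perceive_bonds(out, bond_scale)
    return out


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector a onto unit vector b."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis normal to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _rotation_matrix(perp, 180.0)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def normal_mode_frames(
    mol: Molecule,
    mode: np.ndarray,
    amplitude: float,
    nframes: int,
) -> Molecule:
    """Animate a vibrational normal mode as trajectory frames:
    frame k = R0 + amplitude * sin(2*pi*k/nframes) * d."""
    mode = np.asarray(mode, dtype=float)
    if mode.shape != (mol.n_atoms, 3):
        raise ValueError("one displacement triple per atom required")
    if nframes < 1:
        raise ValueError("nframes must be >= 1")
    out = mol.copy()
    r0 = out.positions
    frames = [
        r0 + amplitude * math.sin(2.0 * math.pi * k / nframes) * mode
        for k in range(nframes)
    ]
    out.set_frames(frames)
    return out


def load_fragment(path: str | Path) -> Molecule:
    """Load a fragment file (native dialect) with link/ref metadata."""
    from .formats import read_axyz

    doc = read_axyz(path)
    if "link_atom" not in doc.molecule.metadata:
        raise ValueError(f"fragment file {path} lacks link_atom metadata")
    return doc.molecule


def fragment_library(directory: str | Path) -> dict[str, Molecule]:
    """All fragments found in a directory of native-dialect files."""
    directory = Path(directory)
    out = {}
    for p in sorted(directory.glob("*.axyz")):
        out[p.stem] = load_fragment(p)
    return out
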