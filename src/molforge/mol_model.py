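"""Core molecular data model.

Molecules are ordered lists of atoms (real elements or ``"X"`` dummy
pivots) with Cartesian positions in angstrom, an optional point charge
per atom, a set of display bonds, optional trajectory frames and free
metadata. Atom ids are the 0-based list positions; deletions compact
the ids and report an old->new map.

Bonds are perceived geometrically: two non-dummy atoms are bonded when
their distance does not exceed ``scale`` times the sum of their
covalent radii. This is a display/grouping heuristic, not a bond-order
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .periodic import DUMMY, covalent_radius, is_element

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "Selection",
    "Group",
    "perceive_bonds",
    "select",
    "mark_group",
]


@dataclass
class Atom:
    element: str
    position: np.ndarray
    charge: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if self.element != DUMMY and not is_element(self.element):
            raise ValueError(f"unknown element symbol: {self.element!r}")

    @property
    def is_dummy(self) -> bool:
        return self.element == DUMMY

    def copy(self) -> "Atom":
        return Atom(self.element, self.position.copy(), self.charge)


@dataclass(frozen=True, order=True)
class Bond:
    a: int
    b: int
    kind: str = "single"

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-bond not allowed")
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @staticmethod
    def make(a: int, b: int, kind: str = "single") -> "Bond":
        lo, hi = (a, b) if a < b else (b, a)
        return Bond(lo, hi, kind)


class Molecule:
    """Ordered atoms + bonds + optional trajectory frames + metadata."""

    def __init__(
        self,
        atoms: Iterable[Atom] = (),
        bonds: Iterable[Bond] = (),
        frames: Sequence[np.ndarray] | None = None,
        metadata: dict | None = None,
    ) -> None:
        self.atoms: list[Atom] = [a for a in atoms]
        self.bonds: set[Bond] = set(bonds)
        self.metadata: dict = dict(metadata or {})
        self.frames: list[np.ndarray] | None = None
        if frames is not None:
            self.set_frames(frames)
        self._check_bonds()

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of current positions (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_positions(self, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (len(self.atoms), 3):
            raise ValueError("position array shape mismatch")
        for a, p in zip(self.atoms, pos):
            a.position = p.copy()
        if self.frames is not None:
            self.frames[0] = pos.copy()

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge if a.charge is not None else 0.0 for a in self.atoms])

    def formula(self) -> str:
        """Hill-order molecular formula, dummies excluded."""
        counts: dict[str, int] = {}
        for a in self.atoms:
            if not a.is_dummy:
                counts[a.element] = counts.get(a.element, 0) + 1
        parts = []
        for sym in ["C", "H"] + sorted(s for s in counts if s not in ("C", "H")):
            if sym in counts:
                parts.append(sym + (str(counts[sym]) if counts[sym] > 1 else ""))
        return "".join(parts)

    # -- frames ----------------------------------------------------------
    def set_frames(self, frames: Sequence[np.ndarray]) -> None:
        frames = [np.asarray(f, dtype=float) for f in frames]
        for f in frames:
            if f.shape != (len(self.atoms), 3):
                raise ValueError("every frame needs one position per atom")
        if frames and not np.allclose(frames[0], self.positions, atol=1e-12):
            raise ValueError("frame 0 must equal the atoms' current positions")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return 1 if self.frames is None else len(self.frames)

    # -- editing ---------------------------------------------------------
    def copy(self) -> "Molecule":
        m = Molecule(
            [a.copy() for a in self.atoms],
            set(self.bonds),
            metadata=dict(self.metadata),
        )
        if self.frames is not None:
            m.frames = [f.copy() for f in self.frames]
        return m

    def add_atom(self, atom: Atom) -> int:
        self.atoms.append(atom)
        if self.frames is not None:
            self.frames = [
                np.vstack([f, atom.position[None, :]]) for f in self.frames
            ]
        return len(self.atoms) - 1

    def delete_atoms(self, ids: Iterable[int]) -> tuple["Molecule", dict[int, int]]:
        """Remove atoms, compact ids; returns (new molecule, old->new map)."""
        drop = set(ids)
        for i in drop:
            self._check_id(i)
        keep = [i for i in range(len(self.atoms)) if i not in drop]
        mapping = {old: new for new, old in enumerate(keep)}
        bonds = {
            Bond(mapping[b.a], mapping[b.b], b.kind)
            for b in self.bonds
            if b.a not in drop and b.b not in drop
        }
        m = Molecule([self.atoms[i].copy() for i in keep], bonds,
                     metadata=dict(self.metadata))
        if self.frames is not None:
            m.frames = [f[keep].copy() for f in self.frames]
        return m, mapping

    def _check_id(self, i: int) -> None:
        if not (0 <= i < len(self.atoms)):
            raise IndexError(f"atom id {i} out of range (n={len(self.atoms)})")

    def _check_bonds(self) -> None:
        for b in self.bonds:
            self._check_id(b.a)
            self._check_id(b.b)
            if self.atoms[b.a].is_dummy or self.atoms[b.b].is_dummy:
                raise ValueError("dummy atoms cannot be bonded")


FocusKind = Literal["centre", "distance", "angle", "torsion"]
_FOCUS_BY_ARITY: dict[int, FocusKind] = {
    1: "centre",
    2: "distance",
    3: "angle",
    4: "torsion",
}


@dataclass(frozen=True)
class Selection:
    """Ordered 1-4 atom focus; the first atom is the mover for edits."""

    ordered: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.ordered) not in _FOCUS_BY_ARITY:
            raise ValueError("selection must contain 1-4 atoms")
        if len(set(self.ordered)) != len(self.ordered):
            raise ValueError("selection ids must be distinct")

    @property
    def focus(self) -> FocusKind:
        return _FOCUS_BY_ARITY[len(self.ordered)]

    @property
    def mover(self) -> int:
        return self.ordered[0]


OriginRule = Literal["explicit", "same_element", "bonded_to", "side_of_bond"]


@dataclass(frozen=True)
class Group:
    """Unordered marked atom set used for group-scope edits."""

    members: frozenset[int]
    origin_rule: OriginRule = "explicit"


def perceive_bonds(mol: Molecule, scale: float = 1.2) -> set[Bond]:
    """Distance-based bond perception with Cordero covalent radii.

    Atoms i, j (both non-dummy) are bonded iff
    ``|ri - rj| <= scale * (Rcov(i) + Rcov(j))``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    idx = [i for i, a in enumerate(mol.atoms) if not a.is_dummy]
    if len(idx) < 2:
        return set()
    radii = np.array([covalent_radius(mol.atoms[i].element) for i in idx])
    pos = np.array([mol.atoms[i].position for i in idx])
    rmax = scale * 2.0 * radii.max()
    tree = cKDTree(pos)
    bonds: set[Bond] = set()
    for ii, jj in tree.query_pairs(rmax):
        d = float(np.linalg.norm(pos[ii] - pos[jj]))
        if d <= scale * (radii[ii] + radii[jj]):
            bonds.add(Bond.make(idx[ii], idx[jj]))
    return bonds


def select(mol: Molecule, ids: Sequence[int]) -> Selection:
    """Build an ordered selection; arity determines the edit focus."""
    for i in ids:
        mol._check_id(i)
    return Selection(tuple(int(i) for i in ids))


def _bond_graph(mol: Molecule, bonds: set[Bond] | None = None) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from((b.a, b.b) for b in (bonds if bonds is not None else mol.bonds))
    return g


def mark_group(
    mol: Molecule,
    rule: OriginRule,
    *,
    ids: Iterable[int] = (),
    element: str | None = None,
    anchor: int | None = None,
    bond: tuple[int, int] | None = None,
    side: int | None = None,
    bonds: set[Bond] | None = None,
) -> Group:
    """Mark an atom group by rule.

    explicit      -> the given ids
    same_element  -> all atoms of ``element``
    bonded_to     -> ``anchor`` plus its bonded neighbours
    side_of_bond  -> connected component containing ``side`` after
                     deleting ``bond`` from the bond graph (the bond
                     must be a bridge)
    """
    if rule == "explicit":
        for i in ids:
            mol._check_id(i)
        return Group(frozenset(int(i) for i in ids), "explicit")
    if rule == "same_element":
        if element is None:
            raise ValueError("same_element rule needs an element symbol")
        return Group(
            frozenset(i for i, a in enumerate(mol.atoms) if a.element == element),
            "same_element",
        )
    if rule == "bonded_to":
        if anchor is None:
            raise ValueError("bonded_to rule needs an anchor atom")
        mol._check_id(anchor)
        g = _bond_graph(mol, bonds)
        return Group(frozenset({anchor} | set(g.neighbors(anchor))), "bonded_to")
    if rule == "side_of_bond":
        if bond is None or side is None:
            raise ValueError("side_of_bond rule needs a bond and a side atom")
        a, b = bond
        mol._check_id(a)
        mol._check_id(b)
        mol._check_id(side)
        g = _bond_graph(mol, bonds)
        if not g.has_edge(a, b):
            raise ValueError(f"no bond between atoms {a} and {b}")
        g.remove_edge(a, b)
        comp = nx.node_connected_component(g, side)
        if a in comp and b in comp:
            raise ValueError("bond is in a cycle")
        return Group(frozenset(comp), "side_of_bond")
    raise ValueError(f"unknown group rule: {rule!r}")
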