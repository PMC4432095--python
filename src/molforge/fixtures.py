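"""Deterministic generators for every test input.

Idealised molecules (benzene, water, ethane, methane, SiO4, durene),
a layered Ca/Si/O platelet with point charges standing in for a
force-field charge calculation, synthetic Gaussian orbital grids
standing in for quantum-chemistry orbital files, and a water droplet
snapshot with per-molecule dipoles standing in for a Monte Carlo
simulation frame. Same (name, params, seed) -> bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from .edit_internal import attach_fragment
from .fields import ScalarGrid
from .mol_model import Atom, Molecule, perceive_bonds
from .orbital_spaces import OrbitalRecord
from .symmetry_build import SymOp

__all__ = [
    "FixtureSpec",
    "make_molecule",
    "builtin_fragments",
    "make_platelet",
    "make_orbital_set",
    "make_droplet",
    "build_fixture",
]

_TET = np.array([
    [1.0, 1.0, 1.0],
    [1.0, -1.0, -1.0],
    [-1.0, 1.0, -1.0],
    [-1.0, -1.0, 1.0],
]) / math.sqrt(3.0)


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    params: dict = dfield(default_factory=dict)
    seed: int = 0


def _hexagon(radius: float) -> np.ndarray:
    ang = np.radians(60.0 * np.arange(6))
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros(6)], axis=1)


def make_molecule(name: str, **params) -> Molecule:
    """Reference geometries: benzene (C-C 1.39, C-H 1.09, planar),
    water (O-H 0.9572, 104.52 deg), staggered ethane, methane, a
    regular SiO4 tetrahedron (Si-O 1.62) and durene built from benzene
    by four methyl attachments."""
    name = name.lower()
    if name == "benzene":
        cc, ch = params.get("cc", 1.39), params.get("ch", 1.09)
        atoms = [Atom("C", p) for p in _hexagon(cc)]
        atoms += [Atom("H", p) for p in _hexagon(cc + ch)]
        mol = Molecule(atoms, metadata={"title": "benzene"})
        mol.bonds = perceive_bonds(mol)
        return mol
    if name == "water":
        oh, ang = params.get("oh", 0.9572), params.get("angle", 104.52)
        half = math.radians(ang / 2.0)
        atoms = [
            Atom("O", (0.0, 0.0, 0.0)),
            Atom("H", (oh * math.sin(half), 0.0, oh * math.cos(half))),
            Atom("H", (-oh * math.sin(half), 0.0, oh * math.cos(half))),
        ]
        mol = Molecule(atoms, metadata={"title": "water"})
        mol.bonds = perceive_bonds(mol)
        return mol
    if name == "ethane":
        cc, ch = params.get("cc", 1.54), params.get("ch", 1.09)
        theta = math.radians(180.0 - 109.471)  # H tilt from the C-C axis
        atoms = [Atom("C", (0.0, 0.0, cc / 2)), Atom("C", (0.0, 0.0, -cc / 2))]
        for k in range(3):  # top CH3 at torsions 0/120/240
            phi = math.radians(120.0 * k)
            atoms.append(Atom("H", (
                ch * math.sin(theta) * math.cos(phi),
                ch * math.sin(theta) * math.sin(phi),
                cc / 2 + ch * math.cos(theta),
            )))
        for k in range(3):  # bottom CH3 staggered at 60/180/300
            phi = math.radians(120.0 * k + 60.0)
            atoms.append(Atom("H", (
                ch * math.sin(theta) * math.cos(phi),
                ch * math.sin(theta) * math.sin(phi),
                -cc / 2 - ch * math.cos(theta),
            )))
        mol = Molecule(atoms, metadata={"title": "ethane"})
        mol.bonds = perceive_bonds(mol)
        return mol
    if name == "methane":
        ch = params.get("ch", 1.09)
        atoms = [Atom("C", (0.0, 0.0, 0.0))]
        atoms += [Atom("H", ch * d) for d in _TET]
        mol = Molecule(atoms, metadata={"title": "methane"})
        mol.bonds = perceive_bonds(mol)
        return mol
    if name in ("sio4", "silicate"):
        sio = params.get("sio", 1.62)
        atoms = [Atom("Si", (0.0, 0.0, 0.0))]
        atoms += [Atom("O", sio * d) for d in _TET]
        mol = Molecule(atoms, metadata={"title": "SiO4"})
        mol.bonds = perceive_bonds(mol)
        return mol
    if name == "h2":
        d = params.get("hh", 0.74)
        mol = Molecule([Atom("H", (0, 0, 0)), Atom("H", (0, 0, d))])
        mol.bonds = perceive_bonds(mol)
        return mol
    if name == "durene":
        mol = make_molecule("benzene")
        methyl = builtin_fragments()["methyl"]
        for ring_c in (0, 1, 3, 4):  # 1,2,4,5-substitution
            bonds = perceive_bonds(mol)
            hs = [
                (b.b if b.a == ring_c else b.a)
                for b in bonds
                if ring_c in (b.a, b.b)
                and mol.atoms[b.b if b.a == ring_c else b.a].element == "H"
            ]
            mol = attach_fragment(mol, hs[0], methyl)
        mol.metadata["title"] = "durene"
        return mol
    raise ValueError(f"unknown fixture molecule: {name!r}")


def builtin_fragments() -> dict[str, Molecule]:
    """Attachable fragments with link/ref metadata (methyl, hydrogen,
    phenyl); users can add more as native-dialect files."""
    ch = 1.09
    theta = math.radians(109.471)
    atoms = [Atom("C", (0.0, 0.0, 0.0))]
    for k in range(3):
        phi = math.radians(120.0 * k)
        atoms.append(Atom("H", (
            ch * math.sin(theta) * math.cos(phi),
            ch * math.sin(theta) * math.sin(phi),
            ch * math.cos(theta),
        )))
    methyl = Molecule(atoms, metadata={"title": "methyl", "link_atom": 0,
                                       "ref_atom": 1})

    hydrogen = Molecule([Atom("H", (0.0, 0.0, 0.0))],
                        metadata={"title": "hydrogen", "link_atom": 0})

    benz = make_molecule("benzene")
    # drop the hydrogen on ring carbon 0 to open a valence
    phenyl, _ = benz.delete_atoms([6])
    phenyl.bonds = perceive_bonds(phenyl)
    phenyl.metadata = {"title": "phenyl", "link_atom": 0, "ref_atom": 1}
    return {"methyl": methyl, "hydrogen": hydrogen, "phenyl": phenyl}


def make_platelet(n_atoms: int = 9360, seed: int = 0) -> Molecule:
    """Layered Ca/Si/O slab with per-atom point charges.

    A five-atom Si/O/Ca motif is replicated by translation symmetry
    operations over a thin 2-layer grid, then trimmed to exactly
    ``n_atoms``. Charges are drawn per element (Ca +1.5+-0.2,
    Si +1.8+-0.2, O -1.1+-0.2) from a seeded generator and shifted so
    the net charge is exactly zero.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    sio = 1.62
    # CaSiO3-like motif: the element charges (Ca +1.5, Si +1.8, 3 O -1.1)
    # balance, so the zero-net-charge shift stays small
    motif = [("Si", np.zeros(3))]
    motif += [("O", sio * d) for d in _TET[:3]]
    motif.append(("Ca", np.array([2.4, 2.4, 1.2])))
    m = len(motif)
    a, b, c = 4.4, 4.4, 4.8
    nz = 2 if n_atoms > m else 1
    nxy = max(1, math.ceil(math.sqrt(n_atoms / (m * nz))))
    tx = SymOp("translation", np.eye(3), np.array([a, 0.0, 0.0]))
    ty = SymOp("translation", np.eye(3), np.array([0.0, b, 0.0]))
    tz = SymOp("translation", np.eye(3), np.array([0.0, 0.0, c]))
    base = np.array([p for _, p in motif])
    elems: list[str] = []
    pos: list[np.ndarray] = []
    for k in range(nz):
        layer = base if k == 0 else tz.apply(base) if k == 1 else None
        if k > 1:
            layer = base + k * tz.translation
        for i in range(nxy):
            col = layer if i == 0 else layer + i * tx.translation
            for j in range(nxy):
                cell = col if j == 0 else col + j * ty.translation
                pos.extend(cell)
                elems.extend(e for e, _ in motif)
                if len(elems) >= n_atoms:
                    break
            if len(elems) >= n_atoms:
                break
        if len(elems) >= n_atoms:
            break
    elems = elems[:n_atoms]
    pos = np.array(pos[:n_atoms])
    rng = np.random.default_rng(seed)
    ranges = {"Ca": 1.5, "Si": 1.8, "O": -1.1}
    q = np.array([ranges[e] + rng.uniform(-0.2, 0.2) for e in elems])
    q -= q.mean()  # exact zero net charge
    atoms = [Atom(e, p, float(c_)) for e, p, c_ in zip(elems, pos, q)]
    return Molecule(atoms, metadata={"title": f"CaSiO platelet n={n_atoms}"})


def _orbital_lattice(mol: Molecule, step: float, margin: float):
    pos = mol.positions
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    shape = tuple(int(math.ceil((hi[d] - lo[d]) / step)) + 1 for d in range(3))
    axes = np.diag([(hi[d] - lo[d]) / (shape[d] - 1) for d in range(3)])
    return lo, axes, shape


def _eval_combo(centers, coeffs, lo, axes, shape, alpha, kind: str) -> np.ndarray:
    """Gaussian AO combination on the lattice: s = exp(-a r^2),
    px/pz = (x or z relative) * exp(-a r^2)."""
    xs = [lo[d] + axes[d, d] * np.arange(shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    vals = np.zeros(shape)
    for cpos, c in zip(centers, coeffs):
        if c == 0.0:
            continue
        dx, dy, dz = X - cpos[0], Y - cpos[1], Z - cpos[2]
        g = np.exp(-alpha * (dx**2 + dy**2 + dz**2))
        if kind == "s":
            vals += c * g
        elif kind == "pz":
            vals += c * dz * g
        elif kind == "px":
            vals += c * dx * g
        else:
            raise ValueError(kind)
    norm = math.sqrt(float((vals**2).sum()) * abs(np.linalg.det(axes)))
    if norm > 0:
        vals /= norm
    return vals


def make_orbital_set(
    geometry: str | Molecule = "durene",
    step: float = 0.35,
    margin: float = 2.5,
    alpha: float = 0.9,
) -> list[OrbitalRecord]:
    """Synthetic orbital grids standing in for computed orbital files.

    ``"single_s"``: one normalised s Gaussian (quadrature norm ~ 1).
    ``"durene"`` (or a molecule): an 18-orbital set on one shared
    lattice — six pi combinations of pz Gaussians on the six ring
    carbons (odd through the molecular plane) and twelve sigma
    orbitals (s/in-plane-p combinations, even through the plane), with
    plausible energies and occupations.
    """
    if geometry == "single_s":
        mol = Molecule([Atom("He", (0.0, 0.0, 0.0))])
        lo, axes, shape = _orbital_lattice(mol, 0.2, 4.0)
        vals = _eval_combo([np.zeros(3)], [1.0], lo, axes, shape, alpha, "s")
        grid = ScalarGrid(lo, axes, vals, "s orbital")
        return [OrbitalRecord(0, "a", -0.9, 2.0, "inactive", grid)]

    mol = make_molecule(geometry) if isinstance(geometry, str) else geometry
    lo, axes, shape = _orbital_lattice(mol, step, margin)
    if max(axes[d, d] for d in range(3)) > 0.5:
        import warnings

        warnings.warn("lattice too coarse to resolve orbital parity (step > 0.5)")
    ring = mol.positions[:6]  # aromatic carbons are the first six atoms
    heavy = [i for i, at in enumerate(mol.atoms)
             if at.element == "C" and i >= 6]
    # benzene-ring Hueckel-like coefficient sets
    j = np.arange(6)
    csets = [
        np.ones(6),
        np.cos(2 * np.pi * j / 6), np.sin(2 * np.pi * j / 6),
        np.cos(4 * np.pi * j / 6), np.sin(4 * np.pi * j / 6),
        (-1.0) ** j,
    ]
    records: list[OrbitalRecord] = []
    idx = 0
    # 12 sigma orbitals: 6 ring s-combinations, 4 methyl-carbon s, 2 in-plane p
    for k, cs in enumerate(csets):
        g = ScalarGrid(lo, axes, _eval_combo(ring, cs, lo, axes, shape, alpha, "s"),
                       f"sigma ring {k}")
        records.append(OrbitalRecord(idx, "a", -1.1 + 0.05 * k, 2.0,
                                     "inactive", g))
        idx += 1
    for k, hi_ in enumerate(heavy[:4]):
        g = ScalarGrid(lo, axes,
                       _eval_combo([mol.positions[hi_]], [1.0], lo, axes, shape,
                                   alpha, "s"),
                       f"sigma methyl {k}")
        records.append(OrbitalRecord(idx, "a", -0.8 + 0.05 * k, 2.0,
                                     "inactive", g))
        idx += 1
    for k in range(2):
        g = ScalarGrid(lo, axes,
                       _eval_combo(ring, csets[k + 1], lo, axes, shape, alpha, "px"),
                       f"sigma inplane {k}")
        records.append(OrbitalRecord(idx, "a", -0.55 + 0.05 * k, 2.0,
                                     "inactive", g))
        idx += 1
    # 6 pi orbitals: 3 occupied, 3 virtual
    for k, cs in enumerate(csets):
        g = ScalarGrid(lo, axes, _eval_combo(ring, cs, lo, axes, shape, alpha, "pz"),
                       f"pi {k}")
        occ = 2.0 if k < 3 else 0.0
        en = -0.35 + 0.06 * k if k < 3 else 0.12 + 0.08 * (k - 3)
        records.append(OrbitalRecord(idx, "a", en, occ,
                                     "inactive" if k < 3 else "secondary", g))
        idx += 1
    return records


def make_droplet(
    n_molecules: int = 100, radius: float = 20.0, seed: int = 0
) -> Molecule:
    """Water-droplet snapshot: molecule centres packed in a sphere
    (minimum separation 2.5 angstrom) with random unit dipole
    orientations scaled to 1.85 D, stored per molecule in metadata."""
    rng = np.random.default_rng(seed)
    min_sep = 2.5
    centres: list[np.ndarray] = []
    tries = 0
    while len(centres) < n_molecules:
        tries += 1
        if tries > 2000 * n_molecules:
            raise ValueError(
                f"packing infeasible: {n_molecules} molecules in radius {radius}"
            )
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) > radius:
            continue
        if any(np.linalg.norm(p - c) < min_sep for c in centres):
            continue
        centres.append(p)
    water = make_molecule("water")
    wpos = water.positions - water.positions[0]
    bisector = np.array([0.0, 0.0, 1.0])  # H-O-H bisector of the template
    atoms: list[Atom] = []
    dipoles = []
    for c in centres:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        # rotate the template so the bisector (dipole direction) is u
        from .edit_internal import _align_rotation

        R = _align_rotation(bisector, u)
        for el, p in zip(water.elements, wpos @ R.T + c):
            atoms.append(Atom(el, p))
        dipoles.append((c.copy(), 1.85 * u))
    mol = Molecule(atoms, metadata={
        "title": f"water droplet n={n_molecules}",
        "molecule_dipoles": dipoles,
    })
    return mol


def build_fixture(name: str, seed: int = 0, **params):
    """Dispatch a fixture by name (CLI entry point)."""
    if name in ("benzene", "water", "ethane", "methane", "sio4", "durene", "h2"):
        return make_molecule(name, **params)
    if name == "platelet":
        return make_platelet(params.pop("n_atoms", 9360), seed)
    if name == "droplet":
        return make_droplet(params.pop("n_molecules", 100),
                            params.pop("radius", 20.0), seed)
    raise ValueError(f"unknown fixture: {name!r}")
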