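"""Symmetry operations as building tools, plus point-group detection.

A :class:`SymOp` is an affine isometry ``x -> M x + t`` assembled from
selected pivot points (atoms or dummies): inversion through a point
(one pivot), rotation about an axis or translation along a vector (two
pivots), reflection through a plane (three pivots).

``apply_replicate`` copies atoms to their symmetry images and merges
images that land within a threshold of an existing atom (the survivor
takes the average position) — the mechanism behind building, e.g., a
fused bicyclic from a monocycle. ``symmetrize`` uses the same pairing
to make a structure exactly invariant under an order-2 operation.
``detect_point_group`` assigns a Schoenflies symbol by explicit
element search over candidate axes and planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .mol_model import Atom, Group, Molecule, Selection
from .periodic import atomic_mass

__all__ = [
    "SymOp",
    "make_operation",
    "apply_replicate",
    "symmetrize",
    "detect_point_group",
    "PointGroupResult",
    "axis_rotation_order",
]

OpKind = Literal["inversion", "rotation", "reflection", "translation"]


@dataclass(frozen=True)
class SymOp:
    kind: OpKind
    matrix: np.ndarray            # 3x3, orthogonal (det +-1); identity for translation
    translation: np.ndarray       # 3, angstrom
    pivots: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation


def _rotmat(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def _points_of(mol: Molecule, selection: Selection) -> list[np.ndarray]:
    return [mol.atoms[i].position.copy() for i in selection.ordered]


def make_operation(
    mol: Molecule,
    selection: Selection,
    kind: OpKind,
    angle: float | None = None,
    multiple: int = 1,
) -> SymOp:
    """Build a symmetry operation from selected pivot points.

    1 pivot -> inversion through it; 2 pivots -> rotation about the
    axis through both (by ``angle`` degrees) or translation by
    ``multiple`` times the second-minus-first vector; 3 pivots ->
    reflection through their plane.
    """
    pts = _points_of(mol, selection)
    arity = len(pts)
    if kind == "inversion":
        if arity != 1:
            raise ValueError("inversion needs exactly one selected point")
        p = pts[0]
        return SymOp("inversion", -np.eye(3), 2.0 * p, (p,))
    if kind == "rotation":
        if arity != 2:
            raise ValueError("rotation needs exactly two selected points")
        if angle is None:
            raise ValueError("rotation needs an angle in degrees")
        axis = pts[1] - pts[0]
        if np.linalg.norm(axis) < 1e-10:
            raise ValueError("rotation axis pivots coincide")
        M = _rotmat(axis, angle)
        t = pts[0] - M @ pts[0]
        return SymOp("rotation", M, t, (pts[0], pts[1]))
    if kind == "translation":
        if arity != 2:
            raise ValueError("translation needs exactly two selected points")
        return SymOp(
            "translation", np.eye(3), float(multiple) * (pts[1] - pts[0]),
            (pts[0], pts[1]),
        )
    if kind == "reflection":
        if arity != 3:
            raise ValueError("reflection needs exactly three selected points")
        n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        if np.linalg.norm(n) < 1e-10:
            raise ValueError("reflection plane is degenerate: collinear points")
        n = n / np.linalg.norm(n)
        M = np.eye(3) - 2.0 * np.outer(n, n)
        t = pts[0] - M @ pts[0]
        return SymOp("reflection", M, t, tuple(pts))
    raise ValueError(f"unknown operation kind: {kind!r}")


def apply_replicate(
    mol: Molecule,
    op: SymOp,
    targets: Group | None = None,
    merge_threshold: float = 0.3,
) -> Molecule:
    """Replicate atoms to their symmetry images, merging near-duplicates.

    Images within ``merge_threshold`` of an existing atom are paired to
    it greedily nearest-first; the survivor moves to the average of the
    pair and the image is dropped. Merging two different elements is a
    symmetry clash and raises.
    """
    if merge_threshold < 0:
        raise ValueError("merge threshold must be >= 0")
    tids = sorted(targets.members) if targets is not None else list(range(mol.n_atoms))
    out = mol.copy()
    if not tids:
        return out
    images = op.apply(np.array([mol.atoms[i].position for i in tids]))
    existing = out.positions
    # candidate merge pairs (distance, image index, existing atom id)
    cands = []
    if out.n_atoms:
        tree = cKDTree(existing)
        for k, img in enumerate(images):
            for j in tree.query_ball_point(img, merge_threshold):
                d = float(np.linalg.norm(img - existing[j]))
                cands.append((d, k, j))
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    merged_imgs: set[int] = set()
    used_existing: set[int] = set()
    for d, k, j in cands:
        if k in merged_imgs or j in used_existing:
            continue
        src = mol.atoms[tids[k]]
        dst = out.atoms[j]
        if src.is_dummy != dst.is_dummy:
            continue  # a pivot dummy never absorbs or shadows a real atom
        if src.element != dst.element:
            raise ValueError(
                f"symmetry clash between {src.element} and {dst.element}"
            )
        dst.position = 0.5 * (dst.position + images[k])
        merged_imgs.add(k)
        used_existing.add(j)
    for k, img in enumerate(images):
        if k in merged_imgs:
            continue
        src = mol.atoms[tids[k]]
        out.add_atom(Atom(src.element, img, src.charge))
    out.frames = None
    return out


def symmetrize(
    mol: Molecule,
    op: SymOp,
    targets: Group | None = None,
    threshold: float = 0.3,
) -> tuple[Molecule, dict]:
    """Average atoms with their images so the set becomes exactly
    invariant under an order-2 operation (inversion, reflection, C2).

    Each target atom whose image lies within ``threshold`` of a target
    atom (possibly itself) moves to the average of its matched partner
    and that partner's image. Unmatched atoms are left untouched and
    listed in the summary.
    """
    M2 = op.matrix @ op.matrix
    t2 = op.matrix @ op.translation + op.translation
    if not (np.allclose(M2, np.eye(3), atol=1e-9) and np.allclose(t2, 0, atol=1e-9)):
        raise ValueError("symmetrize needs an order-2 operation")
    tids = sorted(targets.members) if targets is not None else list(range(mol.n_atoms))
    out = mol.copy()
    pos = out.positions
    tpos = pos[tids]
    images = op.apply(tpos)
    tree = cKDTree(tpos)
    partner: dict[int, int] = {}
    unmatched: list[int] = []
    for k, img in enumerate(images):
        near = tree.query_ball_point(img, threshold)
        near = [
            j for j in near
            if mol.atoms[tids[j]].element == mol.atoms[tids[k]].element
        ]
        if not near:
            unmatched.append(tids[k])
            continue
        j = min(near, key=lambda j: (float(np.linalg.norm(img - tpos[j])), j))
        partner[k] = j
    newpos = pos.copy()
    for k, j in partner.items():
        # atom tids[j] averaged with the image of its partner k
        newpos[tids[j]] = 0.5 * (tpos[j] + images[k])
    out.set_positions(newpos)
    return out, {"unmatched": unmatched, "n_moved": len(partner)}


# ---------------------------------------------------------------------------
# point-group detection
# ---------------------------------------------------------------------------


@dataclass
class PointGroupResult:
    symbol: str
    order_principal: int = 1
    proper_axes: list = field(default_factory=list)     # (order, unit axis)
    mirror_normals: list = field(default_factory=list)  # unit normals
    has_inversion: bool = False

    def __str__(self) -> str:  # pragma: no cover
        return self.symbol


def _permutes(pos: np.ndarray, elems: Sequence[str], new: np.ndarray, tol: float) -> bool:
    """True iff `new` is the same labelled point set as `pos` within tol."""
    by_el: dict[str, list[int]] = {}
    for i, e in enumerate(elems):
        by_el.setdefault(e, []).append(i)
    for e, idx in by_el.items():
        a = pos[idx]
        b = new[idx]
        tree = cKDTree(a)
        d, j = tree.query(b)
        if np.any(d > tol) or len(set(j.tolist())) != len(idx):
            return False
    return True


def _dedupe_dirs(dirs: list[np.ndarray], cos_tol: float = 1.0 - 1e-6) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for d in dirs:
        n = np.linalg.norm(d)
        if n < 1e-8:
            continue
        u = d / n
        if not any(abs(float(u @ v)) > cos_tol for v in out):
            out.append(u)
    return out


def _candidate_axes(pos: np.ndarray, elems: Sequence[str], tol: float) -> list[np.ndarray]:
    cands: list[np.ndarray] = []
    if len(pos) >= 1:
        inertia = np.zeros((3, 3))
        for p, e in zip(pos, elems):
            m = atomic_mass(e) or 1.0
            inertia += m * (float(p @ p) * np.eye(3) - np.outer(p, p))
        _, vecs = np.linalg.eigh(inertia)
        cands.extend(vecs.T)
    for p in pos:
        cands.append(p)
    n = len(pos)
    if n <= 60:
        for i in range(n):
            for j in range(i + 1, n):
                if elems[i] == elems[j]:
                    cands.append(0.5 * (pos[i] + pos[j]))
                    cands.append(np.cross(pos[i], pos[j]))
    return _dedupe_dirs(cands)


def _mirror_normal_candidates(
    pos: np.ndarray, elems: Sequence[str], axes: list[np.ndarray]
) -> list[np.ndarray]:
    cands: list[np.ndarray] = list(axes)
    n = len(pos)
    if n <= 60:
        for i in range(n):
            for j in range(i + 1, n):
                if elems[i] == elems[j]:
                    cands.append(pos[i] - pos[j])
    return _dedupe_dirs(cands)


def _axis_order(pos, elems, axis, tol, max_order) -> int:
    best = 1
    for k in range(2, max_order + 1):
        M = _rotmat(axis, 360.0 / k)
        if _permutes(pos, elems, pos @ M.T, tol):
            best = k
    return best


def _has_improper(pos, elems, axis, order, tol) -> bool:
    """S_order about axis: rotate by 360/order then reflect through the
    plane normal to the axis."""
    M = _rotmat(axis, 360.0 / order)
    refl = np.eye(3) - 2.0 * np.outer(axis, axis)
    return _permutes(pos, elems, pos @ (refl @ M).T, tol)


def axis_rotation_order(
    mol: Molecule,
    point: np.ndarray,
    direction: np.ndarray,
    tol: float = 0.1,
    max_order: int = 8,
) -> int:
    """Largest n such that rotation by 360/n about the given axis maps
    the molecule onto itself (1 if none)."""
    keep = [i for i, a in enumerate(mol.atoms) if not a.is_dummy]
    pos = mol.positions[keep] - np.asarray(point, dtype=float)
    elems = [mol.atoms[i].element for i in keep]
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    return _axis_order(pos, elems, u, tol, max_order)


def detect_point_group(
    mol: Molecule, tol: float = 0.1, max_order: int = 8
) -> PointGroupResult:
    """Schoenflies point group by explicit symmetry-element search.

    The molecule is centred on its mass-weighted centroid; candidate
    proper axes come from the inertia eigenvectors, atom positions and
    same-element pair midpoints/crosses; an element is accepted iff it
    maps the labelled atom set onto itself within ``tol`` angstrom.
    Translations are never considered. Worst case returns C1.
    """
    keep = [i for i, a in enumerate(mol.atoms) if not a.is_dummy]
    if not keep:
        raise ValueError("point group needs at least one non-dummy atom")
    elems = [mol.atoms[i].element for i in keep]
    pos = mol.positions[keep]
    masses = np.array([atomic_mass(e) for e in elems])
    com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
    pos = pos - com

    if len(pos) == 1:
        return PointGroupResult("Kh")

    inv = _permutes(pos, elems, -pos, tol)

    # linear?
    ref = None
    for p in pos:
        if np.linalg.norm(p) > tol:
            ref = p / np.linalg.norm(p)
            break
    if ref is not None and all(
        np.linalg.norm(np.cross(p, ref)) <= tol for p in pos
    ):
        return PointGroupResult("Dinfh" if inv else "Cinfv", has_inversion=inv)

    axes = _candidate_axes(pos, elems, tol)
    proper: list[tuple[int, np.ndarray]] = []
    for u in axes:
        k = _axis_order(pos, elems, u, tol, max_order)
        if k >= 2:
            proper.append((k, u))

    mirrors = [
        n for n in _mirror_normal_candidates(pos, elems, axes)
        if _permutes(pos, elems, pos @ (np.eye(3) - 2.0 * np.outer(n, n)).T, tol)
    ]
    mirrors = _dedupe_dirs(mirrors)

    res = PointGroupResult("C1", proper_axes=proper, mirror_normals=mirrors,
                           has_inversion=inv)

    high = [a for a in proper if a[0] >= 3]
    if len(high) >= 2:
        n5 = sum(1 for k, _ in proper if k >= 5)
        n4 = sum(1 for k, _ in proper if k >= 4)
        if n5 >= 2:
            res.symbol = "Ih" if inv else "I"
        elif n4 >= 2:
            res.symbol = "Oh" if inv else "O"
        else:
            res.symbol = "Th" if inv else ("Td" if mirrors else "T")
        res.order_principal = max(k for k, _ in proper)
        return res

    if not proper:
        if mirrors:
            res.symbol = "Cs"
        elif inv:
            res.symbol = "Ci"
        else:
            res.symbol = "C1"
        return res

    n, principal = max(proper, key=lambda a: a[0])
    res.order_principal = n
    perp_c2 = [
        u for k, u in proper
        if k >= 2 and abs(float(u @ principal)) < 0.05 and not np.allclose(u, principal)
    ]
    sigma_h = any(abs(float(m @ principal)) > 1.0 - 1e-3 for m in mirrors)
    sigma_v = [m for m in mirrors if abs(float(m @ principal)) < 0.05]

    if len(perp_c2) >= n:
        if sigma_h:
            res.symbol = f"D{n}h"
        elif len(sigma_v) >= n:
            res.symbol = f"D{n}d"
        else:
            res.symbol = f"D{n}"
        return res

    if sigma_h:
        res.symbol = f"C{n}h"
    elif len(sigma_v) >= n:
        res.symbol = f"C{n}v"
    elif _has_improper(pos, elems, principal, 2 * n, tol):
        res.symbol = f"S{2 * n}"
    else:
        res.symbol = f"C{n}"
    return res
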