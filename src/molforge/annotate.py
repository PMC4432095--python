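"""Geometric annotation objects and mesh/scene export.

Annotation primitives (arrow, sphere, plane, triangle, parallelepiped)
are defined by a handful of points — selected atoms or free dummy
points — plus a translucent style. Scenes (meshes, optionally built
from objects) export to ascii PLY with per-vertex colours from a
diverging blue-white-red map symmetric about zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .fields import Mesh, Style

__all__ = [
    "GeomObject",
    "add_object",
    "dipole_arrow",
    "object_to_mesh",
    "export_scene",
    "diverging_colors",
]

ObjectKind = Literal["arrow", "sphere", "plane", "triangle", "parallelepiped"]

_POINT_COUNT = {"arrow": 2, "sphere": 1, "plane": 3, "triangle": 3,
                "parallelepiped": 4}


@dataclass
class GeomObject:
    kind: ObjectKind
    points: np.ndarray                  # (k, 3) angstrom
    style: Style = field(default_factory=Style)
    magnitude: float | None = None      # arrow length scale
    radius: float | None = None         # spheres only

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.kind not in _POINT_COUNT:
            raise ValueError(f"unknown object kind: {self.kind!r}")
        if len(self.points) != _POINT_COUNT[self.kind]:
            raise ValueError(
                f"{self.kind} needs {_POINT_COUNT[self.kind]} points, "
                f"got {len(self.points)}"
            )
        if self.kind == "sphere":
            if self.radius is None or self.radius <= 0:
                raise ValueError("sphere needs a positive radius")
        if self.kind in ("plane", "triangle"):
            n = np.cross(self.points[1] - self.points[0],
                         self.points[2] - self.points[0])
            if np.linalg.norm(n) < 1e-10:
                raise ValueError(f"degenerate {self.kind}: collinear points")


def add_object(
    doc,
    kind: ObjectKind,
    points: Sequence | None = None,
    selection=None,
    style: Style | None = None,
    magnitude: float | None = None,
    radius: float | None = None,
):
    """Append an annotation object to a document; points may come from
    an atom selection (dummies allowed) or be given explicitly."""
    if (points is None) == (selection is None):
        raise ValueError("give exactly one of points / selection")
    if selection is not None:
        points = [doc.molecule.atoms[i].position for i in selection.ordered]
    obj = GeomObject(kind, np.asarray(points, dtype=float),
                     style or Style(), magnitude, radius)
    doc.objects.append(obj)
    return doc


def _dipole_anchor(mol) -> np.ndarray:
    q = np.abs(mol.charges)
    pos = mol.positions
    if q.sum() > 1e-12:
        return (q[:, None] * pos).sum(axis=0) / q.sum()
    return pos.mean(axis=0)


def dipole_arrow(doc, scale: float = 1.0):
    """Add arrow(s) for the molecular dipole(s) in the metadata.

    A single ``dipole`` (Debye 3-vector) yields one arrow anchored at
    the charge-weighted centroid (geometric centroid if no charges),
    with direction along the dipole and length |mu| * scale. A
    ``molecule_dipoles`` list of (center, dipole) pairs yields one
    arrow per entry. Zero dipoles add nothing.
    """
    meta = doc.molecule.metadata
    entries = []
    if "dipole" in meta:
        mu = np.asarray(meta["dipole"], dtype=float).reshape(3)
        entries.append((_dipole_anchor(doc.molecule), mu))
    for center, mu in meta.get("molecule_dipoles", []):
        entries.append((np.asarray(center, dtype=float),
                        np.asarray(mu, dtype=float)))
    for anchor, mu in entries:
        norm = float(np.linalg.norm(mu))
        if norm < 1e-12:
            continue
        tip = anchor + scale * mu
        doc.objects.append(
            GeomObject("arrow", np.array([anchor, tip]),
                       Style((0.9, 0.6, 0.1), 0.9), magnitude=norm)
        )
    return doc


# ---------------------------------------------------------------------------
# tessellation + export
# ---------------------------------------------------------------------------


def _frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(float(u @ a)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def object_to_mesh(obj: GeomObject, resolution: int = 12) -> Mesh:
    """Triangulate an annotation object for export."""
    p = obj.points
    if obj.kind in ("triangle", "plane"):
        return Mesh(p.copy(), np.array([[0, 1, 2]]), style=obj.style)
    if obj.kind == "parallelepiped":
        o, a, b, c = p
        ea, eb, ec = a - o, b - o, c - o
        corners = np.array([
            o, o + ea, o + eb, o + ea + eb,
            o + ec, o + ea + ec, o + eb + ec, o + ea + eb + ec,
        ])
        quads = [(0, 1, 3, 2), (4, 5, 7, 6), (0, 1, 5, 4),
                 (2, 3, 7, 6), (0, 2, 6, 4), (1, 3, 7, 5)]
        tris = []
        for q in quads:
            tris.append([q[0], q[1], q[2]])
            tris.append([q[0], q[2], q[3]])
        return Mesh(corners, np.array(tris), style=obj.style)
    if obj.kind == "sphere":
        center, r = p[0], float(obj.radius)
        verts, tris = _uv_sphere(resolution)
        return Mesh(center + r * verts, tris, style=obj.style)
    if obj.kind == "arrow":
        return _arrow_mesh(p[0], p[1], obj.style, resolution)
    raise ValueError(obj.kind)


def _uv_sphere(res: int) -> tuple[np.ndarray, np.ndarray]:
    verts, tris = [], []
    for i in range(res + 1):
        th = math.pi * i / res
        for j in range(res):
            ph = 2 * math.pi * j / res
            verts.append([math.sin(th) * math.cos(ph),
                          math.sin(th) * math.sin(ph), math.cos(th)])
    def vid(i, j):
        return i * res + (j % res)
    for i in range(res):
        for j in range(res):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            if i > 0:
                tris.append([a, b, c])
            if i < res - 1:
                tris.append([b, d, c])
    return np.array(verts), np.array(tris)


def _arrow_mesh(tail: np.ndarray, tip: np.ndarray, style: Style, res: int) -> Mesh:
    v = tip - tail
    length = np.linalg.norm(v)
    if length < 1e-12:
        raise ValueError("zero-length arrow")
    u = v / length
    e1, e2 = _frame(u)
    shaft_r = 0.03 * length
    head_r = 0.08 * length
    head_len = 0.25 * length
    base = tail + (length - head_len) * u
    verts: list[np.ndarray] = []
    tris: list[list[int]] = []
    ring0, ring1, ring2 = [], [], []
    for j in range(res):
        ph = 2 * math.pi * j / res
        off_s = math.cos(ph) * e1 + math.sin(ph) * e2
        ring0.append(len(verts)); verts.append(tail + shaft_r * off_s)
        ring1.append(len(verts)); verts.append(base + shaft_r * off_s)
        ring2.append(len(verts)); verts.append(base + head_r * off_s)
    i_tail = len(verts); verts.append(tail)
    i_tip = len(verts); verts.append(tip)
    for j in range(res):
        k = (j + 1) % res
        tris.append([ring0[j], ring1[j], ring1[k]])
        tris.append([ring0[j], ring1[k], ring0[k]])
        tris.append([ring1[j], ring2[j], ring2[k]])
        tris.append([ring1[j], ring2[k], ring1[k]])
        tris.append([ring2[j], i_tip, ring2[k]])
        tris.append([ring0[j], ring0[k], i_tail])
    return Mesh(np.array(verts), np.array(tris), style=style)


def diverging_colors(scalars: np.ndarray) -> np.ndarray:
    """Blue-white-red RGB, symmetric about zero (limits +-max|s|)."""
    s = np.asarray(scalars, dtype=float)
    vmax = float(np.abs(s).max()) if s.size else 0.0
    if vmax <= 0:
        return np.full((len(s), 3), 255, dtype=np.uint8)
    t = np.clip(s / vmax, -1.0, 1.0)
    rgb = np.empty((len(s), 3))
    neg = t < 0
    # blue (-1) -> white (0) -> red (+1)
    rgb[neg, 0] = 1.0 + t[neg]
    rgb[neg, 1] = 1.0 + t[neg]
    rgb[neg, 2] = 1.0
    rgb[~neg, 0] = 1.0
    rgb[~neg, 1] = 1.0 - t[~neg]
    rgb[~neg, 2] = 1.0 - t[~neg]
    return np.round(255 * rgb).astype(np.uint8)


def export_scene(
    meshes: Mesh | Iterable[Mesh],
    path: str | Path,
    objects: Iterable[GeomObject] = (),
) -> Path:
    """Write an ascii PLY scene with per-vertex RGBA.

    Vertices with scalars get the diverging colormap (symmetric about
    0); others take their mesh's style colour. Alpha encodes opacity.
    """
    if isinstance(meshes, Mesh):
        meshes = [meshes]
    meshes = list(meshes) + [object_to_mesh(o) for o in objects]
    all_v, all_f, all_c = [], [], []
    offset = 0
    for m in meshes:
        all_v.append(m.vertices)
        all_f.append(m.triangles + offset)
        if m.vertex_scalar is not None:
            rgb = diverging_colors(m.vertex_scalar)
        else:
            rgb = np.tile(
                np.round(255 * np.asarray(m.style.color)).astype(np.uint8),
                (m.n_vertices, 1),
            )
        alpha = np.full((m.n_vertices, 1),
                        int(round(255 * m.style.opacity)), dtype=np.uint8)
        all_c.append(np.hstack([rgb, alpha]))
        offset += m.n_vertices
    V = np.vstack(all_v) if all_v else np.zeros((0, 3))
    F = np.vstack(all_f) if all_f else np.zeros((0, 3), dtype=int)
    C = np.vstack(all_c) if all_c else np.zeros((0, 4), dtype=np.uint8)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(V)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\n"
                 "property uchar blue\nproperty uchar alpha\n")
        fh.write(f"element face {len(F)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, c in zip(V, C):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} "
                     f"{c[0]} {c[1]} {c[2]} {c[3]}\n")
        for f in F:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    return path
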