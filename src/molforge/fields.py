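"""Volumetric scalar fields and operations on them.

A :class:`ScalarGrid` is a (possibly non-orthogonal) lattice of scalar
values: ``point(i,j,k) = origin + i*axes[0] + j*axes[1] + k*axes[2]``
with values stored C-ordered (last index fastest), all lengths in
angstrom. Operations cover marching-cubes isosurface extraction,
pointwise grid arithmetic, densities from occupied orbitals, point-
charge electrostatic potentials (atomic units), surface colouring and
mirror-parity classification of orbitals (sigma vs pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import cdist
from skimage.measure import marching_cubes

from .periodic import BOHR_PER_ANGSTROM, atomic_number, covalent_radius

__all__ = [
    "ScalarGrid",
    "Mesh",
    "Style",
    "isosurface",
    "signed_isosurfaces",
    "combine_grids",
    "density_from_orbitals",
    "esp_point_charges",
    "color_mesh_by_field",
    "classify_plane_symmetry",
    "promolecule_density",
]


@dataclass
class ScalarGrid:
    origin: np.ndarray          # (3,) angstrom
    axes: np.ndarray            # (3,3) rows are voxel step vectors, angstrom
    values: np.ndarray          # shape (nx, ny, nz), C order (z fastest)
    label: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3-d array")
        if abs(np.linalg.det(self.axes)) < 1e-12:
            raise ValueError("grid axes must be linearly independent")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def index_to_cart(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (n,3) to Cartesian angstrom."""
        return self.origin + np.asarray(idx, dtype=float) @ self.axes

    def cart_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) @ np.linalg.inv(self.axes)

    def interpolator(self) -> RegularGridInterpolator:
        nx_, ny, nz = self.shape
        return RegularGridInterpolator(
            (np.arange(nx_), np.arange(ny), np.arange(nz)),
            self.values,
            bounds_error=False,
            fill_value=None,  # extrapolate; callers clamp explicitly
        )

    def sample(self, points: np.ndarray, clamp: bool = True) -> tuple[np.ndarray, int]:
        """Trilinear sample at Cartesian points; returns (values, n_clamped)."""
        idx = self.cart_to_index(np.atleast_2d(points))
        hi = np.array(self.shape, dtype=float) - 1.0
        clipped = np.clip(idx, 0.0, hi)
        n_out = int(np.sum(np.any(np.abs(idx - clipped) > 1e-9, axis=1)))
        if not clamp and n_out:
            raise ValueError(f"{n_out} sample points outside grid bounds")
        return self.interpolator()(clipped), n_out

    def same_lattice(self, other: "ScalarGrid", tol: float = 1e-9) -> str | None:
        """Return the first differing lattice field name, or None."""
        if self.shape != other.shape:
            return "shape"
        if not np.allclose(self.origin, other.origin, atol=tol):
            return "origin"
        if not np.allclose(self.axes, other.axes, atol=tol):
            return "axes"
        return None


@dataclass
class Style:
    color: tuple[float, float, float] = (0.8, 0.8, 0.8)
    opacity: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.opacity <= 1.0):
            raise ValueError("opacity must lie in [0, 1]")


@dataclass
class Mesh:
    vertices: np.ndarray                 # (nv, 3) angstrom
    triangles: np.ndarray                # (nf, 3) int vertex indices
    vertex_scalar: np.ndarray | None = None
    style: Style = field(default_factory=Style)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def euler_characteristic(self) -> int:
        edges = set()
        for a, b, c in self.triangles:
            for p, q in ((a, b), (b, c), (a, c)):
                edges.add((min(p, q), max(p, q)))
        return self.n_vertices - len(edges) + self.n_triangles


def _drop_degenerate(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    if not len(faces):
        return faces
    v = verts[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )
    return faces[areas > 1e-12]


def isosurface(grid: ScalarGrid, isovalue: float, style: Style | None = None) -> Mesh:
    """Marching-cubes isosurface (classic 15-case table).

    An isovalue outside the grid's value range yields an empty mesh.
    """
    if not np.isfinite(isovalue):
        raise ValueError("isovalue must be finite")
    if min(grid.shape) < 2:
        raise ValueError("grid must have at least 2 points per axis")
    vmin, vmax = float(grid.values.min()), float(grid.values.max())
    if not (vmin < isovalue < vmax):
        return Mesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int),
                    style=style or Style())
    verts, faces, _, _ = marching_cubes(grid.values, isovalue, method="lorensen")
    faces = _drop_degenerate(verts, faces)
    return Mesh(grid.index_to_cart(verts), faces, style=style or Style())


def signed_isosurfaces(
    grid: ScalarGrid, isovalue: float
) -> tuple[Mesh, Mesh]:
    """Isosurface pair at +|v| and -|v| (positive and negative lobes)."""
    v = abs(isovalue)
    return isosurface(grid, v), isosurface(grid, -v)


def combine_grids(
    grids: Sequence[ScalarGrid], coefficients: Sequence[float]
) -> ScalarGrid:
    """Linear combination sum_k c_k * grid_k on a shared lattice."""
    if len(grids) != len(coefficients):
        raise ValueError("one coefficient per grid required")
    if not grids:
        raise ValueError("need at least one grid")
    ref = grids[0]
    for g in grids[1:]:
        diff = ref.same_lattice(g)
        if diff:
            raise ValueError(f"grid lattice mismatch in field: {diff}")
    vals = np.zeros_like(ref.values)
    for c, g in zip(coefficients, grids):
        vals += float(c) * g.values
    label = " + ".join(f"{c:g}*{g.label or 'grid'}" for c, g in zip(coefficients, grids))
    return ScalarGrid(ref.origin.copy(), ref.axes.copy(), vals, label)


def density_from_orbitals(
    orbitals: Iterable[tuple[ScalarGrid, float]]
) -> ScalarGrid:
    """Electron density rho = sum_i n_i * psi_i**2 on a shared lattice."""
    items = list(orbitals)
    if not items:
        raise ValueError("need at least one orbital")
    ref = items[0][0]
    rho = np.zeros_like(ref.values)
    for g, occ in items:
        if occ < 0:
            raise ValueError("occupation numbers must be >= 0")
        diff = ref.same_lattice(g)
        if diff:
            raise ValueError(f"grid lattice mismatch in field: {diff}")
        rho += float(occ) * g.values**2
    return ScalarGrid(ref.origin.copy(), ref.axes.copy(), rho, "density")


def esp_point_charges(
    points: np.ndarray,
    charge_positions: np.ndarray,
    charges: np.ndarray,
    chunk: int = 2048,
) -> np.ndarray:
    """Electrostatic potential V(r) = sum_i q_i / |r - r_i| in hartree/e.

    Positions are in angstrom and converted to bohr internally. The
    evaluation is chunked over points so memory stays bounded; the
    result is independent of the chunk size.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) * BOHR_PER_ANGSTROM
    cpos = np.atleast_2d(np.asarray(charge_positions, dtype=float)) * BOHR_PER_ANGSTROM
    q = np.asarray(charges, dtype=float).ravel()
    if len(q) != len(cpos):
        raise ValueError("one charge per charge position required")
    out = np.empty(len(pts))
    min_sep = 1e-6 * BOHR_PER_ANGSTROM
    for lo in range(0, len(pts), max(1, chunk)):
        hi = min(lo + max(1, chunk), len(pts))
        d = cdist(pts[lo:hi], cpos)
        close = np.argwhere(d < min_sep)
        if close.size:
            pairs = [(int(i + lo), int(j)) for i, j in close[:5]]
            raise ValueError(
                f"evaluation point(s) coincide with charge(s): {pairs}"
            )
        out[lo:hi] = (q[None, :] / d).sum(axis=1)
    return out


def color_mesh_by_field(
    mesh: Mesh,
    fld: ScalarGrid | tuple[np.ndarray, np.ndarray],
) -> tuple[Mesh, dict]:
    """Attach per-vertex scalars from a grid (trilinear) or point charges.

    Vertices outside a grid's bounding box are clamped to the boundary
    and counted in the returned summary.
    """
    summary: dict = {}
    if isinstance(fld, ScalarGrid):
        scal, n_clamped = fld.sample(mesh.vertices, clamp=True)
        summary["clamped_vertices"] = n_clamped
    else:
        cpos, q = fld
        scal = esp_point_charges(mesh.vertices, cpos, q)
        summary["clamped_vertices"] = 0
    colored = Mesh(mesh.vertices.copy(), mesh.triangles.copy(),
                   vertex_scalar=np.asarray(scal, dtype=float),
                   style=mesh.style)
    return colored, summary


def classify_plane_symmetry(
    grid: ScalarGrid,
    point: np.ndarray,
    normal: np.ndarray,
    n_samples: int = 500,
    seed: int = 0,
    agreement: float = 0.95,
) -> str:
    """Classify an orbital grid by reflection parity through a plane.

    Samples paired points (p, mirror(p)); with |psi| above the noise
    floor (1e-6 * max|psi|), antisymmetric pairs vote "pi", symmetric
    pairs vote "sigma". >= ``agreement`` of votes one way decides;
    otherwise "mixed".
    """
    normal = np.asarray(normal, dtype=float).reshape(3)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("plane normal must be nonzero")
    normal = normal / nn
    point = np.asarray(point, dtype=float).reshape(3)
    vmax = float(np.abs(grid.values).max())
    if vmax <= 0:
        raise ValueError("empty orbital: grid has no signal")
    floor = 1e-6 * vmax
    rng = np.random.default_rng(seed)
    shape = np.array(grid.shape, dtype=float)
    votes_sym = votes_anti = 0
    # oversample; pairs whose mirror falls outside the box are skipped
    frac = rng.uniform(0.0, 1.0, size=(4 * n_samples, 3)) * (shape - 1)
    pts = grid.index_to_cart(frac)
    mirr = pts - 2.0 * ((pts - point) @ normal)[:, None] * normal
    midx = grid.cart_to_index(mirr)
    inside = np.all((midx >= 0) & (midx <= shape - 1), axis=1)
    pts, mirr = pts[inside], mirr[inside]
    vp, _ = grid.sample(pts)
    vm, _ = grid.sample(mirr)
    keep = np.abs(vp) > floor
    vp, vm = vp[keep], vm[keep]
    vp, vm = vp[:n_samples], vm[:n_samples]
    if len(vp) == 0:
        raise ValueError("empty orbital: no samples above the noise floor")
    anti = np.abs(vm + vp) < np.abs(vm - vp)
    votes_anti = int(anti.sum())
    votes_sym = len(vp) - votes_anti
    if votes_anti >= agreement * len(vp):
        return "pi"
    if votes_sym >= agreement * len(vp):
        return "sigma"
    return "mixed"


def promolecule_density(
    mol,
    shape: tuple[int, int, int] = (64, 64, 64),
    margin: float = 3.0,
    decay: float = 0.5,
    cutoff: float = 4.0,
) -> ScalarGrid:
    """Promolecule density: sum of spherical exponential atom terms.

    Each non-dummy atom contributes ``Z * exp(-r / decay)`` within
    ``cutoff`` angstrom (local voxel fill, so large systems stay fast).
    A crude but adequate stand-in for molecular electron density when
    only a surface and its shape are needed.
    """
    pos = mol.positions
    keep = [i for i, a in enumerate(mol.atoms) if not a.is_dummy]
    pos = pos[keep]
    zs = np.array([atomic_number(mol.atoms[i].element) for i in keep], dtype=float)
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    shape = tuple(int(s) for s in shape)
    steps = (hi - lo) / (np.array(shape) - 1)
    axes = np.diag(steps)
    vals = np.zeros(shape)
    grids1d = [lo[d] + steps[d] * np.arange(shape[d]) for d in range(3)]
    for p, z in zip(pos, zs):
        sl = []
        for d in range(3):
            i0 = int(np.floor((p[d] - cutoff - lo[d]) / steps[d]))
            i1 = int(np.ceil((p[d] + cutoff - lo[d]) / steps[d])) + 1
            sl.append((max(0, i0), min(shape[d], i1)))
        (x0, x1), (y0, y1), (z0, z1) = sl
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        dx = grids1d[0][x0:x1] - p[0]
        dy = grids1d[1][y0:y1] - p[1]
        dz = grids1d[2][z0:z1] - p[2]
        r = np.sqrt(
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        vals[x0:x1, y0:y1, z0:z1] += z * np.exp(-r / decay) * (r <= cutoff)
    return ScalarGrid(lo, axes, vals, "promolecule density")
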