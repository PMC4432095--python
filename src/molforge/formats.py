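"""File formats: XYZ, the native AXYZ dialect, Gaussian cube, plug-ins.

The native dialect ("AXYZ", extension ``.axyz``, versioned XML root)
keeps the universal XYZ header — the first ``2 + n`` lines of any
AXYZ file are a plain XYZ file, and any plain XYZ file is a valid
AXYZ file with empty sections. Everything beyond the header is a
single XML root whose sections carry dipoles, volumetric grids,
orbital metadata, annotation objects and the saved view. Unknown
sections survive a round-trip untouched.

Foreign formats are delegated to external converter plug-ins,
registered by filename extension in a user-editable YAML config.
"""

from __future__ import annotations

import os
import shlex
import subprocess
import tempfile
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .annotate import GeomObject
from .fields import ScalarGrid, Style
from .mol_model import Atom, Molecule
from .orbital_spaces import OrbitalRecord
from .periodic import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM, atomic_number, symbol_for_z

__all__ = [
    "Document",
    "PluginSpec",
    "read_xyz",
    "write_xyz",
    "read_axyz",
    "write_axyz",
    "read_grid_cube",
    "read_cube",
    "write_grid_cube",
    "load_registry",
    "resolve_plugin",
    "convert_via_plugin",
    "NATIVE_SUFFIXES",
]

NATIVE_SUFFIXES = (".xyz", ".axyz")

AXYZ_ROOT = "axyz"
AXYZ_VERSION = "1.0"

_COORD_FMT = "%.6f"
_VALUE_FMT = "%.10e"


@dataclass
class Document:
    """A molecule plus its visualisable payload sections."""

    molecule: Molecule
    grids: list[ScalarGrid] = dfield(default_factory=list)
    orbitals: list[OrbitalRecord] = dfield(default_factory=list)
    objects: list[GeomObject] = dfield(default_factory=list)
    view: dict | None = None
    extra: list[str] = dfield(default_factory=list)  # unknown XML sections, verbatim


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def _parse_xyz_block(lines: list[str], start: int):
    """Parse one XYZ block starting at ``lines[start]``.

    Returns (elements, positions, charges, title, next_line_index).
    """
    try:
        n = int(lines[start].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"line {start + 1}: expected an atom count") from None
    if n < 0:
        raise ValueError(f"line {start + 1}: negative atom count")
    title = lines[start + 1].rstrip("\n") if start + 1 < len(lines) else ""
    if start + 2 + n > len(lines) and n > 0:
        raise ValueError(
            f"line {start + 1}: atom count {n} exceeds remaining lines"
        )
    elements, positions, charges = [], [], []
    for k in range(n):
        lineno = start + 2 + k
        parts = lines[lineno].split()
        if len(parts) not in (4, 5):
            raise ValueError(f"line {lineno + 1}: expected 'Symbol x y z [charge]'")
        try:
            xyz = [float(v) for v in parts[1:4]]
            q = float(parts[4]) if len(parts) == 5 else None
        except ValueError:
            raise ValueError(
                f"line {lineno + 1}: unparseable coordinate in {parts!r}"
            ) from None
        elements.append(parts[0])
        positions.append(xyz)
        charges.append(q)
    return elements, positions, charges, title, start + 2 + n


def read_xyz(path: str | Path) -> Molecule:
    """Read an XYZ file; concatenated blocks become trajectory frames."""
    text = Path(path).read_text()
    lines = text.splitlines()
    frames: list[np.ndarray] = []
    first = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        elements, positions, charges, title, i = _parse_xyz_block(lines, i)
        pos = np.array(positions, dtype=float).reshape(len(elements), 3)
        if first is None:
            first = (elements, pos, charges, title)
        else:
            if elements != first[0]:
                raise ValueError("trajectory frames must share the atom list")
        frames.append(pos)
    if first is None:
        raise ValueError("empty file: no XYZ block found")
    elements, pos, charges, title = first
    atoms = [Atom(e, p, q) for e, p, q in zip(elements, pos, charges)]
    mol = Molecule(atoms, metadata={"title": title} if title else {})
    if len(frames) > 1:
        mol.set_frames(frames)
    return mol


def _xyz_block_lines(mol: Molecule, pos: np.ndarray, title: str) -> list[str]:
    with_charge = any(a.charge is not None for a in mol.atoms)
    out = [str(mol.n_atoms), title]
    for a, p in zip(mol.atoms, pos):
        line = f"{a.element} " + " ".join(_COORD_FMT % c for c in p)
        if with_charge:
            line += " " + (_COORD_FMT % (a.charge if a.charge is not None else 0.0))
        out.append(line)
    return out


def write_xyz(mol: Molecule, path: str | Path) -> Path:
    """Write XYZ; a molecule with frames writes concatenated blocks."""
    title = str(mol.metadata.get("title", ""))
    frames = mol.frames if mol.frames is not None else [mol.positions]
    lines: list[str] = []
    for f in frames:
        lines.extend(_xyz_block_lines(mol, f, title))
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# AXYZ dialect
# ---------------------------------------------------------------------------


def _fmt_vec(v, fmt=_COORD_FMT) -> str:
    return " ".join(fmt % x for x in np.asarray(v, dtype=float).ravel())


def _grid_xml(g: ScalarGrid) -> list[str]:
    out = [f'  <grid label="{g.label}">']
    out.append(f"    <origin>{_fmt_vec(g.origin)}</origin>")
    for ax in g.axes:
        out.append(f"    <axis>{_fmt_vec(ax)}</axis>")
    out.append(f"    <shape>{g.shape[0]} {g.shape[1]} {g.shape[2]}</shape>")
    vals = g.values.ravel()
    body = []
    for lo in range(0, len(vals), 6):
        body.append(" ".join(_VALUE_FMT % v for v in vals[lo:lo + 6]))
    out.append("    <values>")
    out.extend("      " + b for b in body)
    out.append("    </values>")
    out.append("  </grid>")
    return out


def _parse_grid(el: ET.Element) -> ScalarGrid:
    origin = np.fromstring(el.findtext("origin", ""), sep=" ")
    axes = np.array([np.fromstring(ax.text or "", sep=" ")
                     for ax in el.findall("axis")])
    shape = tuple(int(s) for s in (el.findtext("shape", "")).split())
    vals = np.fromstring(el.findtext("values", ""), sep=" ")
    if vals.size != int(np.prod(shape)):
        raise ValueError(
            f"grid section: {vals.size} values for shape {shape}"
        )
    return ScalarGrid(origin, axes, vals.reshape(shape), el.get("label", ""))


def _object_xml(o: GeomObject) -> list[str]:
    attrs = [f'kind="{o.kind}"',
             f'color="{_fmt_vec(o.style.color)}"',
             f'opacity="{_COORD_FMT % o.style.opacity}"']
    if o.magnitude is not None:
        attrs.append(f'magnitude="{_COORD_FMT % o.magnitude}"')
    if o.radius is not None:
        attrs.append(f'radius="{_COORD_FMT % o.radius}"')
    out = [f"  <object {' '.join(attrs)}>"]
    for p in o.points:
        out.append(f"    <point>{_fmt_vec(p)}</point>")
    out.append("  </object>")
    return out


def _parse_object(el: ET.Element) -> GeomObject:
    pts = np.array([np.fromstring(p.text or "", sep=" ")
                    for p in el.findall("point")])
    color = tuple(np.fromstring(el.get("color", "0.8 0.8 0.8"), sep=" "))
    opacity = float(el.get("opacity", "0.5"))
    mag = el.get("magnitude")
    rad = el.get("radius")
    return GeomObject(
        el.get("kind"), pts, Style(color, opacity),
        float(mag) if mag is not None else None,
        float(rad) if rad is not None else None,
    )


def _meta_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def write_axyz(doc: Document, path: str | Path) -> Path:
    """Serialize a document: XYZ header, then the XML section block."""
    mol = doc.molecule
    title = str(mol.metadata.get("title", ""))
    lines = _xyz_block_lines(mol, mol.positions, title)

    sections: list[str] = []
    if "dipole" in mol.metadata:
        sections.append(
            f'  <dipole unit="debye">{_fmt_vec(mol.metadata["dipole"])}</dipole>'
        )
    for center, mu in mol.metadata.get("molecule_dipoles", []):
        sections.append(
            f'  <moldipole center="{_fmt_vec(center)}" dipole="{_fmt_vec(mu)}"/>'
        )
    for key in sorted(mol.metadata):
        if key in ("title", "dipole", "molecule_dipoles"):
            continue
        sections.append(f'  <meta key="{key}">{mol.metadata[key]}</meta>')
    for g in doc.grids:
        sections.extend(_grid_xml(g))
    if doc.orbitals:
        sections.append("  <orbitals>")
        for r in doc.orbitals:
            attrs = [
                f'index="{r.index}"', f'symmetry="{r.symmetry}"',
                f'energy="{_VALUE_FMT % r.energy}"',
                f'occupation="{_COORD_FMT % r.occupation}"',
                f'subspace="{r.subspace}"',
                f'hidden="{"true" if r.hidden else "false"}"',
            ]
            if r.orbital_type is not None:
                attrs.append(f'type="{r.orbital_type}"')
            gi = next((i for i, g in enumerate(doc.grids) if g is r.grid), None)
            if gi is not None:
                attrs.append(f'grid="{gi}"')
            sections.append(f"    <orbital {' '.join(attrs)}/>")
        sections.append("  </orbitals>")
    for o in doc.objects:
        sections.extend(_object_xml(o))
    if doc.view is not None:
        attrs = " ".join(f'{k}="{v}"' for k, v in sorted(doc.view.items()))
        sections.append(f"  <view {attrs}/>")
    for raw in doc.extra:
        sections.extend("  " + ln for ln in raw.strip().splitlines())

    if sections:
        lines.append(f'<{AXYZ_ROOT} version="{AXYZ_VERSION}">')
        lines.extend(sections)
        lines.append(f"</{AXYZ_ROOT}>")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_axyz(path: str | Path) -> Document:
    """Parse the native dialect; a plain XYZ file gives empty sections."""
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ValueError("empty file")
    first = lines[0].split()[0]
    try:
        int(first)
    except ValueError:
        raise ValueError(
            "missing XYZ header: the file must start with an atom count"
        ) from None
    elements, positions, charges, title, nxt = _parse_xyz_block(lines, 0)
    atoms = [Atom(e, p, q) for e, p, q in zip(elements, positions, charges)]
    mol = Molecule(atoms, metadata={"title": title} if title else {})
    rest = "\n".join(lines[nxt:]).strip()
    doc = Document(mol)
    if not rest:
        return doc
    try:
        root = ET.fromstring(rest)
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML section block after header: {exc}") from None
    for el in root:
        try:
            _read_section(doc, el)
        except Exception as exc:
            raise ValueError(f"bad <{el.tag}> section: {exc}") from exc
    return doc


def _read_section(doc: Document, el: ET.Element) -> None:
    mol = doc.molecule
    if el.tag == "dipole":
        mol.metadata["dipole"] = np.fromstring(el.text or "", sep=" ")
    elif el.tag == "moldipole":
        mol.metadata.setdefault("molecule_dipoles", []).append(
            (np.fromstring(el.get("center", ""), sep=" "),
             np.fromstring(el.get("dipole", ""), sep=" "))
        )
    elif el.tag == "meta":
        mol.metadata[el.get("key")] = _meta_value(el.text or "")
    elif el.tag == "grid":
        doc.grids.append(_parse_grid(el))
    elif el.tag == "orbitals":
        for orb in el.findall("orbital"):
            gi = orb.get("grid")
            doc.orbitals.append(OrbitalRecord(
                index=int(orb.get("index")),
                symmetry=orb.get("symmetry", ""),
                energy=float(orb.get("energy", "0")),
                occupation=float(orb.get("occupation", "0")),
                subspace=orb.get("subspace", "secondary"),
                hidden=orb.get("hidden", "false") == "true",
                orbital_type=orb.get("type"),
                grid=doc.grids[int(gi)] if gi is not None else None,
            ))
    elif el.tag == "object":
        doc.objects.append(_parse_object(el))
    elif el.tag == "view":
        doc.view = {k: _meta_value(v) for k, v in el.attrib.items()}
    else:
        doc.extra.append(ET.tostring(el, encoding="unicode").strip())


# ---------------------------------------------------------------------------
# Gaussian cube
# ---------------------------------------------------------------------------


def read_cube(path: str | Path) -> tuple[ScalarGrid, Molecule]:
    """Read a Gaussian cube file: (grid, atom block). Lengths convert
    from bohr to angstrom at this boundary; values are z-fastest."""
    lines = Path(path).read_text().splitlines()
    label = lines[0].strip()
    natoms_f = lines[2].split()
    natoms = int(natoms_f[0])
    origin = np.array([float(v) for v in natoms_f[1:4]]) * ANGSTROM_PER_BOHR
    dims, axes = [], []
    for k in range(3):
        parts = lines[3 + k].split()
        dims.append(abs(int(parts[0])))
        axes.append([float(v) * ANGSTROM_PER_BOHR for v in parts[1:4]])
    atoms = []
    for k in range(abs(natoms)):
        parts = lines[6 + k].split()
        z = int(parts[0])
        q = float(parts[1])
        p = np.array([float(v) for v in parts[2:5]]) * ANGSTROM_PER_BOHR
        atoms.append(Atom(symbol_for_z(z), p, q if q else None))
    vals = np.fromstring(" ".join(lines[6 + abs(natoms):]), sep=" ")
    expect = dims[0] * dims[1] * dims[2]
    if vals.size != expect:
        raise ValueError(
            f"cube voxel count {vals.size} inconsistent with header {dims}"
        )
    grid = ScalarGrid(origin, np.array(axes), vals.reshape(dims), label)
    return grid, Molecule(atoms, metadata={"title": label} if label else {})


def read_grid_cube(path: str | Path) -> ScalarGrid:
    return read_cube(path)[0]


def write_grid_cube(
    grid: ScalarGrid, path: str | Path, mol: Molecule | None = None
) -> Path:
    """Write a Gaussian cube file (bohr, z-fastest)."""
    lines = [grid.label or "volumetric data", "written by molforge"]
    atoms = [a for a in (mol.atoms if mol is not None else []) if not a.is_dummy]
    o = grid.origin * BOHR_PER_ANGSTROM
    lines.append(f"{len(atoms):5d} " + " ".join("%.10f" % v for v in o))
    for n, ax in zip(grid.shape, grid.axes):
        lines.append(
            f"{n:5d} " + " ".join("%.10f" % (v * BOHR_PER_ANGSTROM) for v in ax)
        )
    for a in atoms:
        p = a.position * BOHR_PER_ANGSTROM
        q = a.charge if a.charge is not None else 0.0
        lines.append(
            f"{atomic_number(a.element):5d} %.6f " % q
            + " ".join("%.10f" % v for v in p)
        )
    vals = grid.values.ravel()
    for lo in range(0, len(vals), 6):
        lines.append(" ".join(_VALUE_FMT % v for v in vals[lo:lo + 6]))
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# plug-in converters
# ---------------------------------------------------------------------------

Direction = Literal["import", "export", "compute"]


@dataclass(frozen=True)
class PluginSpec:
    format_name: str
    command: str                      # template with {in} and {out}
    extensions: tuple[str, ...]
    direction: Direction = "import"

    def __post_init__(self) -> None:
        if "{in}" not in self.command or "{out}" not in self.command:
            raise ValueError(
                f"plug-in {self.format_name!r}: command template must "
                "contain both {in} and {out} placeholders"
            )


def load_registry(path: str | Path) -> list[PluginSpec]:
    """Load the plug-in registry from a YAML config file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    specs = []
    seen: dict[str, str] = {}
    for entry in data.get("plugins", []):
        spec = PluginSpec(
            format_name=entry["name"],
            command=entry["command"],
            extensions=tuple(entry.get("extensions", [])),
            direction=entry.get("direction", "import"),
        )
        for ext in spec.extensions:
            key = f"{ext}:{spec.direction}"
            if key in seen:
                raise ValueError(
                    f"extension {ext!r} registered by both "
                    f"{seen[key]!r} and {spec.format_name!r}"
                )
            seen[key] = spec.format_name
        specs.append(spec)
    return specs


def resolve_plugin(
    registry: Sequence[PluginSpec],
    path: str | Path,
    explicit_format: str | None = None,
    direction: Direction = "import",
) -> PluginSpec | None:
    """Pick the plug-in for a file; None means the format is native.

    An explicit format name wins; otherwise the longest matching
    registered suffix; native suffixes (.xyz, .axyz) bypass plug-ins.
    """
    if explicit_format is not None:
        if explicit_format in ("xyz", "axyz"):
            return None
        for spec in registry:
            if spec.format_name == explicit_format and spec.direction == direction:
                return spec
        raise ValueError(f"no plug-in named {explicit_format!r}")
    name = str(path)
    if any(name.endswith(suf) for suf in NATIVE_SUFFIXES):
        return None
    best: PluginSpec | None = None
    best_len = -1
    for spec in registry:
        if spec.direction != direction:
            continue
        for ext in spec.extensions:
            if name.endswith(ext) and len(ext) > best_len:
                best, best_len = spec, len(ext)
    if best is None:
        known = sorted(
            ext for s in registry if s.direction == direction for ext in s.extensions
        )
        raise ValueError(
            f"no plug-in for extension of {name!r}; known extensions: {known}"
        )
    return best


def convert_via_plugin(
    spec: PluginSpec,
    in_path: str | Path,
    out_path: str | Path | None = None,
    timeout: float = 60.0,
):
    """Run a converter plug-in.

    import/compute: the command writes a native file to a temp path,
    which is parsed and returned as a Document (the temp is removed).
    export: the command writes ``out_path`` in the foreign format.
    """
    in_path = Path(in_path)
    if spec.direction in ("import", "compute"):
        fd, tmp = tempfile.mkstemp(suffix=".axyz")
        os.close(fd)
        try:
            _run_plugin(spec, in_path, Path(tmp), timeout)
            return read_axyz(tmp)
        finally:
            os.unlink(tmp)
    if out_path is None:
        raise ValueError("export plug-ins need an output path")
    _run_plugin(spec, in_path, Path(out_path), timeout)
    return Path(out_path)


def _run_plugin(spec: PluginSpec, inp: Path, outp: Path, timeout: float) -> None:
    argv = [
        tok.replace("{in}", str(inp)).replace("{out}", str(outp))
        for tok in shlex.split(spec.command)
    ]
    try:
        proc = subprocess.run(
            argv, capture_output=True, text=True, timeout=timeout
        )
    except FileNotFoundError:
        raise RuntimeError(
            f"plug-in {spec.format_name!r}: executable {argv[0]!r} not found"
        ) from None
    except subprocess.TimeoutExpired:
        raise RuntimeError(
            f"plug-in {spec.format_name!r} timed out after {timeout} s"
        ) from None
    if proc.returncode != 0:
        raise RuntimeError(
            f"plug-in {spec.format_name!r} exited {proc.returncode}: "
            f"{proc.stderr.strip() or proc.stdout.strip()}"
        )
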