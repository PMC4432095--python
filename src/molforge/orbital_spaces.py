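"""Orbital metadata bookkeeping for multiconfigurational active spaces.

Orbitals carry symmetry (irrep label), energy, occupation and a
subspace tag from the restricted-active-space partition: frozen,
inactive, RAS1, RAS2, RAS3, secondary, deleted. Operations cover
filtering by type/symmetry/energy/occupancy, (re)assigning subspaces
and exporting a RAS-style input block (per-irrep counts plus a
per-orbital type-index string).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .fields import ScalarGrid

__all__ = [
    "OrbitalRecord",
    "SUBSPACES",
    "filter_orbitals",
    "assign_subspace",
    "subspace_counts",
    "export_ras_spec",
]

SUBSPACES = ("frozen", "inactive", "ras1", "ras2", "ras3", "secondary", "deleted")

_TYPE_LETTER = {
    "frozen": "f",
    "inactive": "i",
    "ras1": "1",
    "ras2": "2",
    "ras3": "3",
    "secondary": "s",
    "deleted": "d",
}


@dataclass(frozen=True)
class OrbitalRecord:
    index: int
    symmetry: str = ""
    energy: float = 0.0               # hartree
    occupation: float = 0.0           # electrons, in [0, 2]
    subspace: str = "secondary"
    grid: ScalarGrid | None = None
    hidden: bool = False
    orbital_type: str | None = None   # "sigma" / "pi" / "mixed" when classified

    def __post_init__(self) -> None:
        if self.subspace not in SUBSPACES:
            raise ValueError(f"unknown subspace: {self.subspace!r}")
        if not (0.0 <= self.occupation <= 2.0):
            raise ValueError("occupation must lie in [0, 2]")


def filter_orbitals(
    records: Sequence[OrbitalRecord],
    orbital_type: str | None = None,
    symmetry: str | None = None,
    energy_window: tuple[float, float] | None = None,
    occupancy_window: tuple[float, float] | None = None,
    subspace: str | None = None,
    include_hidden: bool = False,
) -> list[OrbitalRecord]:
    """Conjunction of the given criteria, original order preserved.

    Hidden records are excluded unless ``include_hidden``. No criteria
    -> the full visible list.
    """
    out = []
    for r in records:
        if r.hidden and not include_hidden:
            continue
        if orbital_type is not None and r.orbital_type != orbital_type:
            continue
        if symmetry is not None and r.symmetry != symmetry:
            continue
        if energy_window is not None and not (
            energy_window[0] <= r.energy <= energy_window[1]
        ):
            continue
        if occupancy_window is not None and not (
            occupancy_window[0] <= r.occupation <= occupancy_window[1]
        ):
            continue
        if subspace is not None and r.subspace != subspace:
            continue
        out.append(r)
    return out


def assign_subspace(
    records: Sequence[OrbitalRecord],
    ids: Iterable[int],
    subspace: str,
) -> list[OrbitalRecord]:
    """Return records with the listed orbital indices moved to
    ``subspace``; other records untouched."""
    if subspace not in SUBSPACES:
        raise ValueError(f"unknown subspace: {subspace!r}")
    ids = set(ids)
    known = {r.index for r in records}
    missing = ids - known
    if missing:
        raise ValueError(f"unknown orbital index(es): {sorted(missing)}")
    return [
        replace(r, subspace=subspace) if r.index in ids else r for r in records
    ]


def subspace_counts(
    records: Sequence[OrbitalRecord], by_symmetry: bool = False
) -> dict:
    """Counts per subspace; with ``by_symmetry``, per (subspace, irrep)."""
    out: dict = {}
    for r in records:
        key = (r.subspace, r.symmetry) if by_symmetry else r.subspace
        out[key] = out.get(key, 0) + 1
    return out


def export_ras_spec(
    records: Sequence[OrbitalRecord],
    symmetry_order: Sequence[str] | None = None,
) -> str:
    """Emit a RAS-style active-space block.

    Per-subspace per-irrep counts as keyword lines (Frozen, Inactive,
    Ras1, Ras2, Ras3, Deleted) in the given irrep order, followed by a
    ``TypeIndex`` string with one letter per orbital (f,i,1,2,3,s,d) in
    index order. The dialect is this package's own, versioned; it
    follows common RAS input conventions without claiming byte
    compatibility with any particular code.
    """
    recs = sorted(records, key=lambda r: r.index)
    irreps = list(dict.fromkeys(r.symmetry for r in recs))
    if symmetry_order is None:
        symmetry_order = irreps
    if len(set(irreps)) > 1 and any(r.symmetry == "" for r in recs):
        raise ValueError(
            "orbital with missing symmetry label while several irreps present"
        )
    unknown = set(irreps) - set(symmetry_order)
    if unknown:
        raise ValueError(f"irrep(s) missing from symmetry order: {sorted(unknown)}")
    counts = subspace_counts(recs, by_symmetry=True)
    lines = ["* RAS subspace specification (molforge dialect v1)"]
    for sub, kw in [
        ("frozen", "Frozen"),
        ("inactive", "Inactive"),
        ("ras1", "Ras1"),
        ("ras2", "Ras2"),
        ("ras3", "Ras3"),
        ("deleted", "Deleted"),
    ]:
        per_irrep = [str(counts.get((sub, ir), 0)) for ir in symmetry_order]
        lines.append(f"{kw}= {' '.join(per_irrep)}")
    type_string = "".join(_TYPE_LETTER[r.subspace] for r in recs)
    lines.append(f"TypeIndex= {type_string}")
    return "\n".join(lines) + "\n"
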