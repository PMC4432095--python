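"""Element data: symbols, atomic numbers, masses, covalent radii.

Covalent radii are the Cordero 2008 single-bond values in angstrom
(C is the sp3 value; Mn, Fe, Co are the high-spin values). Masses are
standard atomic weights. The dummy-atom token is ``"X"``: dummies carry
no mass, no radius and never participate in bonds.
"""

from __future__ import annotations

DUMMY = "X"

# symbol -> (Z, mass / u, covalent radius / angstrom)
_ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 0.31),
    "He": (2, 4.0026, 0.28),
    "Li": (3, 6.94, 1.28),
    "Be": (4, 9.0122, 0.96),
    "B": (5, 10.81, 0.84),
    "C": (6, 12.011, 0.76),
    "N": (7, 14.007, 0.71),
    "O": (8, 15.999, 0.66),
    "F": (9, 18.998, 0.57),
    "Ne": (10, 20.180, 0.58),
    "Na": (11, 22.990, 1.66),
    "Mg": (12, 24.305, 1.41),
    "Al": (13, 26.982, 1.21),
    "Si": (14, 28.085, 1.11),
    "P": (15, 30.974, 1.07),
    "S": (16, 32.06, 1.05),
    "Cl": (17, 35.45, 1.02),
    "Ar": (18, 39.948, 1.06),
    "K": (19, 39.098, 2.03),
    "Ca": (20, 40.078, 1.76),
    "Sc": (21, 44.956, 1.70),
    "Ti": (22, 47.867, 1.60),
    "V": (23, 50.942, 1.53),
    "Cr": (24, 51.996, 1.39),
    "Mn": (25, 54.938, 1.61),
    "Fe": (26, 55.845, 1.52),
    "Co": (27, 58.933, 1.50),
    "Ni": (28, 58.693, 1.24),
    "Cu": (29, 63.546, 1.32),
    "Zn": (30, 65.38, 1.22),
    "Ga": (31, 69.723, 1.22),
    "Ge": (32, 72.630, 1.20),
    "As": (33, 74.922, 1.19),
    "Se": (34, 78.971, 1.20),
    "Br": (35, 79.904, 1.20),
    "Kr": (36, 83.798, 1.16),
    "Rb": (37, 85.468, 2.20),
    "Sr": (38, 87.62, 1.95),
    "Y": (39, 88.906, 1.90),
    "Zr": (40, 91.224, 1.75),
    "Nb": (41, 92.906, 1.64),
    "Mo": (42, 95.95, 1.54),
    "Tc": (43, 98.0, 1.47),
    "Ru": (44, 101.07, 1.46),
    "Rh": (45, 102.91, 1.42),
    "Pd": (46, 106.42, 1.39),
    "Ag": (47, 107.87, 1.45),
    "Cd": (48, 112.41, 1.44),
    "In": (49, 114.82, 1.42),
    "Sn": (50, 118.71, 1.39),
    "Sb": (51, 121.76, 1.39),
    "Te": (52, 127.60, 1.38),
    "I": (53, 126.90, 1.39),
    "Xe": (54, 131.29, 1.40),
    "Cs": (55, 132.91, 2.44),
    "Ba": (56, 137.33, 2.15),
    "La": (57, 138.91, 2.07),
    "W": (74, 183.84, 1.62),
    "Re": (75, 186.21, 1.51),
    "Os": (76, 190.23, 1.44),
    "Ir": (77, 192.22, 1.41),
    "Pt": (78, 195.08, 1.36),
    "Au": (79, 196.97, 1.36),
    "Hg": (80, 200.59, 1.32),
    "Tl": (81, 204.38, 1.45),
    "Pb": (82, 207.2, 1.46),
    "Bi": (83, 208.98, 1.48),
    "U": (92, 238.03, 1.96),
}

_BY_Z: dict[int, str] = {z: sym for sym, (z, _, _) in _ELEMENTS.items()}

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the data table."""


def is_element(symbol: str) -> bool:
    return symbol in _ELEMENTS


def _lookup(symbol: str) -> tuple[int, float, float]:
    try:
        return _ELEMENTS[symbol]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from None


def atomic_number(symbol: str) -> int:
    if symbol == DUMMY:
        return 0
    return _lookup(symbol)[0]


def atomic_mass(symbol: str) -> float:
    if symbol == DUMMY:
        return 0.0
    return _lookup(symbol)[1]


def covalent_radius(symbol: str) -> float:
    """Cordero single-bond covalent radius in angstrom."""
    return _lookup(symbol)[2]


def symbol_for_z(z: int) -> str:
    if z == 0:
        return DUMMY
    try:
        return _BY_Z[z]
    except KeyError:
        raise UnknownElementError(f"no symbol for atomic number {z}") from None
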