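"""Per-element constants used throughout the package.

Masses are standard atomic weights (Da).  Van der Waals radii follow the
Bondi compilation, with the common extensions for metals.  Electron counts
(atomic numbers) serve as the q-independent X-ray form factors of the
Debye scattering calculation.
"""

from __future__ import annotations

import warnings

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}

#: Bondi van der Waals radii (A).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "NA": 2.27, "MG": 1.73, "P": 1.80, "S": 1.80, "CL": 1.75, "K": 2.75,
    "CA": 2.31, "MN": 2.05, "FE": 2.05, "CO": 2.00, "NI": 1.63,
    "CU": 1.40, "ZN": 1.39, "SE": 1.90, "BR": 1.85, "I": 1.98,
}

ELECTRON_COUNTS: dict[str, int] = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}

_DEFAULT_MASS = 12.011
_DEFAULT_RADIUS = 1.70
_DEFAULT_ELECTRONS = 6

#: Three-letter codes of the twenty standard amino acids.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)

_TWO_LETTER = frozenset(
    e for e in ATOMIC_MASSES if len(e) == 2
)


def normalize_element(symbol: str) -> str:
    return symbol.strip().upper()


def guess_element(atom_name: str, resname: str = "") -> str:
    """Infer the element symbol from a PDB atom name.

    For standard amino-acid residues the element is the first alphabetic
    character of the stripped name (so ``CA`` is carbon, not calcium).
    Otherwise two-letter symbols such as ``ZN``/``FE``/``CL`` are tried
    before falling back to the first letter.
    """
    name = atom_name.strip().upper()
    alpha = "".join(ch for ch in name if ch.isalpha())
    if not alpha:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if resname.strip().upper() in STANDARD_RESIDUES:
        return alpha[0]
    if alpha[:2] in _TWO_LETTER and name == alpha:
        return alpha[:2]
    return alpha[0]


def mass_of(element: str) -> float:
    el = normalize_element(element)
    try:
        return ATOMIC_MASSES[el]
    except KeyError:
        warnings.warn(f"unknown element {element!r}: using generic mass")
        return _DEFAULT_MASS


def vdw_radius_of(element: str) -> float:
    el = normalize_element(element)
    try:
        return VDW_RADII[el]
    except KeyError:
        warnings.warn(f"unknown element {element!r}: using generic vdW radius")
        return _DEFAULT_RADIUS


def electrons_of(element: str) -> int:
    el = normalize_element(element)
    try:
        return ELECTRON_COUNTS[el]
    except KeyError:
        warnings.warn(f"unknown element {element!r}: using generic form factor")
        return _DEFAULT_ELECTRONS
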