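"""Resolution of reference crystal-structure coordinates.

The SMYD3 validation targets (radius of gyration and maximum dimension of
PDB entry 3PDN; Calpha RMSD between 3PDN and 5CCL) need the deposited
coordinates, which this package does not bundle.  Place the PDB files in a
directory (default ``./reference_structures`` or ``$MDSTATES_REFDATA``) —
e.g. downloaded from https://files.rcsb.org/download/3PDN.pdb — and
:func:`load_reference_structure` will pick them up.
"""

from __future__ import annotations

import os
from pathlib import Path

from .core import Structure
from .io import read_pdb

__all__ = ["load_reference_structure", "protein_heavy_atom_indices"]


def _search_dirs() -> list[Path]:
    dirs = []
    env = os.environ.get("MDSTATES_REFDATA")
    if env:
        dirs.append(Path(env))
    dirs.append(Path.cwd() / "reference_structures")
    return dirs


def load_reference_structure(pdb_id: str) -> Structure:
    """Load a reference structure by PDB id from the local search path.

    Raises :class:`FileNotFoundError` with download guidance when the
    coordinates are not available locally (no network access is attempted).
    """
    pdb_id = pdb_id.lower()
    for d in _search_dirs():
        for name in (f"{pdb_id}.pdb", f"{pdb_id.upper()}.pdb"):
            path = d / name
            if path.exists():
                return read_pdb(path)
    searched = ", ".join(str(d) for d in _search_dirs())
    raise FileNotFoundError(
        f"reference structure {pdb_id.upper()} not available locally "
        f"(searched: {searched}); download "
        f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb into one of "
        "those directories"
    )


def protein_heavy_atom_indices(s: Structure) -> list[int]:
    """Indices of standard-residue heavy atoms (no waters, ions, ligands,
    hydrogens) — the atom set used for crystal-structure Rg/Dmax."""
    from .elements import STANDARD_RESIDUES

    return [
        i
        for i, a in enumerate(s.atoms)
        if a.resname.strip().upper() in STANDARD_RESIDUES and a.element != "H"
    ]
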