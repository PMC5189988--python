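"""Readers and writers for PDB (single- and multi-model) and DCD files.

PDB reading is delegated to MDAnalysis; DCD I/O uses mdtraj's low-level
``DCDTrajectoryFile`` (coordinates only, Angstroms).  Alternate locations
are resolved to the highest-occupancy conformer (ties keep the first).
Masses and van der Waals radii are assigned from the bundled element
tables, never guessed from the file.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np

from . import elements
from .core import (
    Atom,
    EmptyStructureError,
    PDBParseError,
    Structure,
    TopologyError,
    Trajectory,
    TrajectoryError,
)

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_dcd",
    "write_dcd",
]


def _first_bad_pdb_line(path: str | os.PathLike) -> str | None:
    """Locate the first ATOM/HETATM record with malformed coordinates."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        return f"line {lineno}: {line.rstrip()}"
    return None


def _universe(path: str | os.PathLike):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path))
    except Exception as exc:
        bad = _first_bad_pdb_line(path)
        if bad is not None:
            raise PDBParseError(f"malformed PDB record at {bad}") from exc
        raise PDBParseError(f"could not parse {path}: {exc}") from exc


def _atoms_from_universe(u) -> list[Atom]:
    ag = u.atoms
    n = len(ag)
    if n == 0:
        raise EmptyStructureError("PDB file contains no atoms")
    names = ag.names
    resnames = ag.resnames
    resids = ag.resids
    try:
        chains = ag.chainIDs
    except Exception:
        chains = ag.segids
    try:
        occ = np.asarray(ag.occupancies, dtype=float)
    except Exception:
        occ = np.ones(n)
    try:
        altlocs = np.asarray(ag.altLocs)
    except Exception:
        altlocs = np.array([""] * n)
    try:
        file_elements = [str(e).strip() for e in ag.elements]
    except Exception:
        file_elements = [""] * n

    # altloc resolution: per (chain, resid, name) keep highest occupancy,
    # ties keep the first occurrence.
    keep = np.ones(n, dtype=bool)
    groups: dict[tuple, int] = {}
    for i in range(n):
        if not str(altlocs[i]).strip():
            continue
        key = (str(chains[i]), int(resids[i]), str(names[i]))
        j = groups.get(key)
        if j is None:
            groups[key] = i
        elif occ[i] > occ[j]:
            keep[j] = False
            groups[key] = i
        else:
            keep[i] = False

    positions = ag.positions
    atoms: list[Atom] = []
    serial = 0
    for i in range(n):
        if not keep[i]:
            continue
        serial += 1
        el = file_elements[i]
        if not el:
            el = elements.guess_element(str(names[i]), str(resnames[i]))
        el = elements.normalize_element(el)
        atoms.append(
            Atom(
                serial=serial,
                name=str(names[i]).strip(),
                element=el,
                resname=str(resnames[i]).strip(),
                resid=int(resids[i]),
                chain=str(chains[i]).strip(),
                coords=positions[i],
                mass=elements.mass_of(el),
                radius=elements.vdw_radius_of(el),
            )
        )
    return atoms


def read_pdb(path: str | os.PathLike) -> Structure:
    """Read the first MODEL of a PDB file into a :class:`Structure`."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        if not any(line.startswith(("ATOM", "HETATM")) for line in fh):
            raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    u = _universe(path)
    atoms = _atoms_from_universe(u)
    return Structure(atoms, title=Path(path).stem)


def _format_atom_name(name: str, element: str) -> str:
    # PDB column alignment: single-letter elements start in column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(
    path: str | os.PathLike,
    structure: Structure,
    coords: np.ndarray | None = None,
) -> None:
    """Write a structure, or a multi-model ensemble, to PDB.

    ``coords`` may be ``(A, 3)`` or ``(F, A, 3)``; the latter produces one
    MODEL per frame.  Omitting it writes the structure's own coordinates.
    """
    if coords is None:
        frames = structure.coords[None]
    else:
        coords = np.asarray(coords, dtype=float)
        frames = coords[None] if coords.ndim == 2 else coords
    if frames.shape[1:] != (structure.n_atoms, 3):
        raise ValueError("coordinate array does not match atom count")
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title[:60]}\n")
        for m, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:>4}\n")
            for a, xyz in zip(structure.atoms, frame):
                name = _format_atom_name(a.name, a.element)
                fh.write(
                    f"ATOM  {a.serial % 100000:>5} {name} {a.resname:>3} "
                    f"{(a.chain or 'A')[:1]}{a.resid % 10000:>4}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_dcd(path: str | os.PathLike, traj: Trajectory) -> None:
    """Write trajectory coordinates to a DCD file (Angstroms)."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path), "w") as fh:
        fh.write(np.asarray(traj.coords, dtype=np.float32))


def read_dcd(path: str | os.PathLike, topology: Structure) -> Trajectory:
    """Read a DCD file; times are assigned at 1-ps spacing (DCD frames
    written by this package carry no time metadata)."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path)) as fh:
        xyz, _, _ = fh.read()
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 3 or xyz.shape[0] < 2:
        raise TrajectoryError(f"{path}: fewer than 2 frames")
    if xyz.shape[1] != topology.n_atoms:
        raise TopologyError(
            f"{path}: {xyz.shape[1]} atoms per frame, topology has {topology.n_atoms}"
        )
    times = np.arange(xyz.shape[0], dtype=float)
    return Trajectory(xyz, times, topology)


def _read_multimodel_pdb(path: str | os.PathLike, topology: Structure) -> Trajectory:
    u = _universe(path)
    if len(u.atoms) != topology.n_atoms:
        raise TopologyError(
            f"{path}: {len(u.atoms)} atoms per model, topology has {topology.n_atoms}"
        )
    frames = []
    times = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # "no dt information" on plain PDB models
        for ts in u.trajectory:
            frames.append(ts.positions.copy())
            times.append(float(ts.time))
    if len(frames) < 2:
        raise TrajectoryError(f"{path}: fewer than 2 models")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):  # no usable time metadata in the file
        times = np.arange(len(frames), dtype=float)
    return Trajectory(np.asarray(frames, dtype=float), times, topology)


def read_trajectory(path: str | os.PathLike, topology: Structure) -> Trajectory:
    """Read a multi-model PDB or DCD trajectory against a topology."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if str(path).lower().endswith(".dcd"):
        return read_dcd(path, topology)
    return _read_multimodel_pdb(path, topology)


def write_trajectory(path: str | os.PathLike, traj: Trajectory) -> None:
    if str(path).lower().endswith(".dcd"):
        write_dcd(path, traj)
    else:
        write_pdb(path, traj.topology, traj.coords)
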