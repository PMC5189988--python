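"""Domain types shared by every analysis stage.

A :class:`Structure` is an ordered list of :class:`Atom` records (one
conformation plus atom metadata); a :class:`Trajectory` is an
``F x A x 3`` coordinate stack in Angstroms that shares a structure as its
topology.  :class:`AtomSelection` is a validated, sorted index list into a
structure's atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np


class MDStatesError(Exception):
    """Base class of all package-specific errors."""


class PDBParseError(MDStatesError):
    pass


class EmptyStructureError(MDStatesError):
    pass


class TopologyError(MDStatesError):
    pass


class TrajectoryError(MDStatesError):
    pass


class SelectionError(MDStatesError):
    pass


class CapabilityError(MDStatesError):
    """A computation requires input the structure cannot provide
    (e.g. hydrogen-based H-bond geometry on a hydrogen-free structure)."""


class ConstructionError(MDStatesError):
    pass


class AlignmentError(MDStatesError):
    """Frame indices of an attribute series do not align with state labels."""


@dataclass
class Atom:
    """A single atom: identity, coordinates (A), mass (Da), vdW radius (A)."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    coords: np.ndarray
    mass: float
    radius: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.serial}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if not self.mass > 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")
        if not self.radius > 0:
            raise ValueError(f"atom {self.serial}: radius must be positive")


@dataclass
class Structure:
    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise EmptyStructureError("structure contains no atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials are not unique")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """``(A, 3)`` coordinate array (copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [
            Atom(a.serial, a.name, a.element, a.resname, a.resid, a.chain,
                 coords[i], a.mass, a.radius)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, self.title if title is None else title)

    def residues(self) -> Iterator[tuple[tuple[str, int, str], list[int]]]:
        """Iterate ``((chain, resid, resname), atom_indices)`` in file order."""
        seen: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            seen.setdefault((a.chain, a.resid, a.resname), []).append(i)
        yield from seen.items()

    def find_atom(self, resid: int, name: str, chain: str | None = None) -> int | None:
        for i, a in enumerate(self.atoms):
            if a.resid == resid and a.name == name and (chain is None or a.chain == chain):
                return i
        return None


@dataclass
class AtomSelection:
    """Sorted, unique atom indices into a structure, with a label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise SelectionError("selection indices must be 1-D")
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise SelectionError("selection indices must be sorted and unique")
        if idx.size and idx.min() < 0:
            raise SelectionError("negative selection index")
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate(self, structure_or_n: "Structure | int") -> None:
        n = structure_or_n if isinstance(structure_or_n, int) else structure_or_n.n_atoms
        if self.indices.size and self.indices.max() >= n:
            raise SelectionError("selection index out of range")


@dataclass
class Trajectory:
    """F frames x A atoms x 3 Cartesian coordinates (A), times in ps."""

    coords: np.ndarray
    times: np.ndarray
    topology: Structure

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (F, A, 3)")
        if self.coords.shape[0] < 2:
            raise TrajectoryError("a trajectory needs at least 2 frames")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"trajectory has {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.times.shape != (self.coords.shape[0],):
            raise TrajectoryError("times length must equal frame count")
        if np.any(np.diff(self.times) <= 0):
            raise TrajectoryError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def subset(self, frames: Sequence[int] | np.ndarray) -> "Trajectory":
        frames = np.asarray(frames, dtype=int)
        return Trajectory(self.coords[frames], self.times[frames], self.topology)


@dataclass
class AttributeSeries:
    """A per-frame time course of one structural attribute.

    ``frame_index`` records which trajectory frames the (possibly strided)
    values belong to.  Binary kinds (``hbond``, ``saltbridge``, ``contact``)
    hold only 0/1.
    """

    id: str
    kind: str
    values: np.ndarray
    frame_index: np.ndarray

    BINARY_KINDS = frozenset({"hbond", "saltbridge", "contact"})
    KINDS = BINARY_KINDS | frozenset({"phi", "psi", "sasa", "distance"})

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.values.shape != self.frame_index.shape:
            raise ValueError("values and frame_index lengths differ")
        if self.kind in self.BINARY_KINDS:
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ValueError(f"{self.kind} series must be binary 0/1")


@dataclass
class StateLabels:
    """Per-frame binary conformational-state labels: 0 = closed, 1 = open."""

    labels: np.ndarray
    method: str = ""
    transition_frame: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("state labels must be non-negative")
        if self.transition_frame is not None:
            n0 = int(np.sum(self.labels == 0))
            n1 = int(np.sum(self.labels == 1))
            if n0 == 0 or n1 == 0:
                raise ValueError("a reported transition requires both states")

    def __len__(self) -> int:
        return int(self.labels.size)


def longest_run_start(binary: np.ndarray, value: int = 1) -> int | None:
    """First index of the longest run of ``value``; None if absent."""
    x = np.asarray(binary) == value
    if not x.any():
        return None
    # run-length encode
    padded = np.concatenate(([0], x.astype(int), [0]))
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    best = int(np.argmax(ends - starts))
    return int(starts[best])
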