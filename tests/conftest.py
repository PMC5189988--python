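"""Shared fixtures: programmatic structures and one default synthetic run."""

from __future__ import annotations

import numpy as np
import pytest

from mdstates import elements
from mdstates.core import Atom, Structure, Trajectory
from mdstates.geometry import fit_trajectory
from mdstates.selections import select
from mdstates.synthetic import GeneratorConfig, simulate_trajectory


def make_atom(serial, name, resname, resid, xyz, chain="A", element=None):
    el = element or elements.guess_element(name, resname)
    return Atom(
        serial=serial,
        name=name,
        element=el,
        resname=resname,
        resid=resid,
        chain=chain,
        coords=np.asarray(xyz, dtype=float),
        mass=elements.mass_of(el),
        radius=elements.vdw_radius_of(el),
    )


def make_structure(spec):
    """Build a Structure from (name, resname, resid, xyz[, chain]) tuples."""
    atoms = []
    for k, entry in enumerate(spec):
        name, resname, resid, xyz = entry[:4]
        chain = entry[4] if len(entry) > 4 else "A"
        atoms.append(make_atom(k + 1, name, resname, resid, xyz, chain))
    return Structure(atoms)


def make_trajectory(structure, frames):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(frames, np.arange(frames.shape[0], dtype=float), structure)


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration synthetic run shared across tests."""
    traj, truth = simulate_trajectory(GeneratorConfig(seed=1))
    return traj, truth


@pytest.fixture(scope="session")
def fitted_ca(default_sim):
    """The default run least-squares fitted to frame 0 over Calpha atoms."""
    traj, truth = default_sim
    sel = select(traj.topology, "name CA")
    return fit_trajectory(traj, sel), sel, truth


@pytest.fixture
def tripeptide():
    """Three-residue backbone-only peptide (no hydrogens)."""
    spec = []
    for r in range(3):
        base = np.array([3.8 * r, 0.0, 0.0])
        spec += [
            ("N", "ALA", r + 1, base + [0.0, 0.5, 0.0]),
            ("CA", "ALA", r + 1, base + [1.2, 1.2, 0.0]),
            ("C", "ALA", r + 1, base + [2.4, 0.6, 0.3]),
            ("O", "ALA", r + 1, base + [2.6, -0.6, 0.4]),
        ]
    return make_structure(spec)
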