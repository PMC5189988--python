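"""Ground-truth generator: two-lobe, two-state hinge trajectories.

The generator emulates a two-lobe protein that interconverts between a
compact "closed" reference and an "open" reference related by a rigid
rotation of the second lobe about a hinge axis at the lobe interface.  The
trajectory switches state sharply at a configured transition frame and
adds isotropic Gaussian thermal noise.  Designed, recoverable ground truth
is embedded on top of the hinge motion:

* contact pairs placed at a short distance in the closed reference and a
  long one in the open reference (state-specific contacts);
* residues whose backbone psi angle is resampled each frame from a
  state-specific von Mises distribution (state-specific dihedrals);
* one residue pair whose thermal noise is correlated +rho in the closed
  state and -rho in the open state (a switching correlated pair, the
  target of the running-cross-correlation deviation map).

The model is a poly-alanine-like backbone (N, CA, C, O, H per residue) on
a compact serpentine lattice; it is geometrically plausible but carries no
force field — the noise is statistical, not physical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import elements
from .core import ConstructionError, StateLabels, Structure, Trajectory, Atom
from .geometry import dihedral
from .states import HingeResult

__all__ = [
    "ContactPair",
    "DihedralShift",
    "CorrelationPair",
    "GeneratorConfig",
    "GroundTruth",
    "make_two_lobe_model",
    "simulate_trajectory",
]

_CA_SPACING = 3.8  # A, consecutive-residue lattice spacing

# local atom offsets relative to CA (A); bond-length-plausible, not ideal
_OFFSETS = {
    "N": np.array([-1.20, -0.80, 0.30]),
    "C": np.array([1.10, 0.80, -0.25]),
    "O": np.array([1.55, 1.85, -0.55]),
}
_H_FROM_N = np.array([-0.60, -0.80, 0.00])  # |.| = 1.0 A


@dataclass(frozen=True)
class ContactPair:
    """A designed state-specific contact: residues (closed lobe indices)
    held at ``closed_distance`` in the closed reference and
    ``open_distance`` in the open one (Calpha-Calpha)."""

    res_a: int
    res_b: int
    closed_distance: float = 4.2
    open_distance: float = 12.0


@dataclass(frozen=True)
class DihedralShift:
    """A residue whose psi is resampled per frame from von Mises
    distributions with state-specific means (degrees)."""

    resid: int
    closed_psi: float = -60.0
    open_psi: float = 120.0
    kappa: float = 50.0


@dataclass(frozen=True)
class CorrelationPair:
    """A residue pair with correlated thermal noise: +rho while closed,
    -rho while open (rho in (0, 1))."""

    res_a: int
    res_b: int
    rho: float = 0.8


@dataclass
class GeneratorConfig:
    n_residues_per_lobe: int = 100
    theta: float = 25.0  # open-state hinge rotation, degrees
    n_frames: int = 2000
    transition_frame: int = 1000
    noise_sigma: float = 0.3  # A per coordinate
    #: shared rigid-body (translational) noise per lobe, A: the semi-rigid
    #: domain motion that gives residues of one lobe correlated dynamics
    lobe_noise_sigma: float = 0.3
    hinge_point: np.ndarray | None = None  # default: interface centre
    hinge_direction: np.ndarray | None = None  # default: +z
    contact_pairs: tuple[ContactPair, ...] | None = None
    dihedral_shifts: tuple[DihedralShift, ...] | None = None
    correlation_pairs: tuple[CorrelationPair, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.transition_frame < self.n_frames):
            raise ValueError("transition_frame must lie inside the trajectory")
        if not (0 <= self.theta < 180):
            raise ValueError("theta must be in [0, 180) degrees; 0 is the identity")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        n = self.n_residues_per_lobe
        if self.contact_pairs is None:
            # three interface-spanning pairs: lobe A residues face lobe B ones
            self.contact_pairs = tuple(
                ContactPair(*_iface_pair(n, k)) for k in range(3)
            )
        if self.dihedral_shifts is None:
            self.dihedral_shifts = (
                DihedralShift(n + n // 2),
                DihedralShift(n + n // 2 + 5, closed_psi=150.0, open_psi=-30.0),
            )
        if self.correlation_pairs is None:
            self.correlation_pairs = (CorrelationPair(n // 2, n + n // 3),)


@dataclass
class GroundTruth:
    labels: StateLabels
    hinge: HingeResult
    designed_attribute_ids: list[str]
    lobe_assignment: dict[int, str]  # resid -> "N-lobe" | "C-lobe"
    contact_pairs: tuple[ContactPair, ...] = ()
    dihedral_shifts: tuple[DihedralShift, ...] = ()
    correlation_pairs: tuple[CorrelationPair, ...] = ()


def _lattice_dims(n: int) -> tuple[int, int, int]:
    nx = max(2, int(round(n ** (1 / 3))))
    ny = nx
    nz = int(np.ceil(n / (nx * ny)))
    return nx, ny, nz


def _serpentine_lattice(n: int) -> np.ndarray:
    """Compact serpentine CA path through an nx x ny x nz lattice so that
    sequence neighbours stay lattice neighbours."""
    nx, ny, nz = _lattice_dims(n)
    pts = []
    for k in range(nz):
        for j in range(ny):
            xs = range(nx) if (j + k) % 2 == 0 else range(nx - 1, -1, -1)
            for i in xs:
                pts.append((i, j if k % 2 == 0 else ny - 1 - j, k))
                if len(pts) == n:
                    return np.asarray(pts, dtype=float) * _CA_SPACING
    return np.asarray(pts[:n], dtype=float) * _CA_SPACING


def _face_residues(n: int, far_face: bool) -> list[int]:
    """1-based residue indices (within one lobe) on the +x face
    (``far_face=True``) or the x=0 face of the serpentine lattice."""
    nx, _, _ = _lattice_dims(n)
    lat = _serpentine_lattice(n)
    target = (nx - 1) * _CA_SPACING if far_face else 0.0
    return [i + 1 for i in range(n) if abs(lat[i, 0] - target) < 1e-9]


def _iface_pair(n: int, k: int) -> tuple[int, int]:
    """k-th designed interface pair: a lobe-A residue on its +x face and
    the facing lobe-B residue on its x=0 face (global 1-based resids)."""
    face_a = _face_residues(n, far_face=True)
    face_b = _face_residues(n, far_face=False)
    step_a = max(1, len(face_a) // 4)
    step_b = max(1, len(face_b) // 4)
    ra = face_a[(1 + k * step_a) % len(face_a)]
    rb = face_b[(1 + k * step_b) % len(face_b)]
    return ra, n + rb


def _residue_atoms(serial0: int, resid: int, chain: str, ca: np.ndarray) -> list[Atom]:
    atoms = []
    spec = [("N", _OFFSETS["N"]), ("CA", np.zeros(3)), ("C", _OFFSETS["C"]),
            ("O", _OFFSETS["O"]), ("H", _OFFSETS["N"] + _H_FROM_N)]
    for k, (name, off) in enumerate(spec):
        el = name[0] if name != "CA" else "C"
        atoms.append(
            Atom(
                serial=serial0 + k,
                name=name,
                element=el,
                resname="ALA",
                resid=resid,
                chain=chain,
                coords=ca + off,
                mass=elements.mass_of(el),
                radius=elements.vdw_radius_of(el),
            )
        )
    return atoms


_LOBE_GAP = 5.5  # A between lobe faces: close enough for a persistent seam


def _hinge_geometry(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Hinge point and unit direction (config override or interface default)."""
    n = cfg.n_residues_per_lobe
    la = _serpentine_lattice(n)
    nx, _, _ = _lattice_dims(n)
    if cfg.hinge_point is not None:
        point = np.asarray(cfg.hinge_point, dtype=float)
    else:
        point = np.array([(nx - 1) * _CA_SPACING + _LOBE_GAP / 2.0,
                          la[:, 1].mean(), la[:, 2].mean()])
    if cfg.hinge_direction is not None:
        direction = np.asarray(cfg.hinge_direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
    else:
        direction = np.array([0.0, 0.0, 1.0])
    return point, direction


def _base_model(cfg: GeneratorConfig) -> Structure:
    """Unadjusted closed-state structure."""
    n = cfg.n_residues_per_lobe
    la = _serpentine_lattice(n)
    nx, _, _ = _lattice_dims(n)
    shift = np.array([(nx - 1) * _CA_SPACING + _LOBE_GAP, 0.0, 0.0])
    cas = np.vstack([la, la + shift])
    atoms: list[Atom] = []
    for r in range(2 * n):
        atoms.extend(_residue_atoms(5 * r + 1, r + 1, "A", cas[r]))
    return Structure(atoms, title="synthetic two-lobe model (closed)")


def _lobe_atom_mask(s: Structure, n_per_lobe: int) -> np.ndarray:
    resids = np.array([a.resid for a in s.atoms])
    return resids > n_per_lobe  # True for lobe B (C-lobe)


def _apply_contact(
    coords: np.ndarray, s: Structure, pair: ContactPair, target: float
) -> np.ndarray:
    """Rigidly translate residue ``res_b`` so its CA sits ``target`` A from
    ``res_a``'s CA along their current separation vector."""
    ia = s.find_atom(pair.res_a, "CA")
    ib = s.find_atom(pair.res_b, "CA")
    if ia is None or ib is None:
        raise ConstructionError(f"contact pair {pair.res_a}-{pair.res_b}: residue missing")
    if target <= 0:
        raise ConstructionError(
            f"contact pair {pair.res_a}-{pair.res_b}: non-positive target distance"
        )
    v = coords[ib] - coords[ia]
    dist = np.linalg.norm(v)
    if dist < 1e-9:
        raise ConstructionError(
            f"contact pair {pair.res_a}-{pair.res_b}: coincident residues"
        )
    delta = (target / dist - 1.0) * v
    out = coords.copy()
    members = [i for i, a in enumerate(s.atoms) if a.resid == pair.res_b]
    out[members] += delta
    return out


def make_two_lobe_model(cfg: GeneratorConfig) -> tuple[Structure, Structure]:
    """Closed and open reference structures.

    The open reference equals the closed one with lobe B rotated by
    ``theta`` about the hinge axis; designed contact pairs are then placed
    at their state-specific distances (these per-residue adjustments are
    the only deviation from a pure rigid rotation).
    """
    base = _base_model(cfg)
    point, direction = _hinge_geometry(cfg)
    coords_closed = base.coords
    rot = Rotation.from_rotvec(np.radians(cfg.theta) * direction)
    mask = _lobe_atom_mask(base, cfg.n_residues_per_lobe)
    coords_open = coords_closed.copy()
    coords_open[mask] = rot.apply(coords_closed[mask] - point) + point
    for pair in cfg.contact_pairs:
        coords_closed = _apply_contact(coords_closed, base, pair, pair.closed_distance)
        coords_open = _apply_contact(coords_open, base, pair, pair.open_distance)
    closed_ref = base.with_coords(coords_closed)
    open_ref = base.with_coords(coords_open, title="synthetic two-lobe model (open)")
    return closed_ref, open_ref


def _set_psi(coords: np.ndarray, s: Structure, resid: int, target_deg: float) -> None:
    """Rotate the next residue's N about this residue's CA-C axis so the
    psi dihedral equals ``target_deg`` (in place)."""
    i_n = s.find_atom(resid, "N")
    i_ca = s.find_atom(resid, "CA")
    i_c = s.find_atom(resid, "C")
    i_nn = s.find_atom(resid + 1, "N")
    if None in (i_n, i_ca, i_c, i_nn):
        raise ConstructionError(f"residue {resid}: psi atoms missing")
    current = float(dihedral(coords[i_n], coords[i_ca], coords[i_c], coords[i_nn]))
    axis = coords[i_c] - coords[i_ca]
    axis = axis / np.linalg.norm(axis)
    delta = np.radians(target_deg - current)
    rot = Rotation.from_rotvec(delta * axis)
    coords[i_nn] = rot.apply(coords[i_nn] - coords[i_c]) + coords[i_c]
    achieved = float(dihedral(coords[i_n], coords[i_ca], coords[i_c], coords[i_nn]))
    if abs((achieved - target_deg + 180) % 360 - 180) > 1e-6:
        rot = Rotation.from_rotvec(-2 * delta * axis)
        coords[i_nn] = rot.apply(coords[i_nn] - coords[i_c]) + coords[i_c]


def simulate_trajectory(cfg: GeneratorConfig) -> tuple[Trajectory, GroundTruth]:
    """Simulate the two-state trajectory with designed ground truth.

    Frame t uses the closed reference before ``transition_frame`` and the
    open one after (sharp transition); designed psi residues are resampled
    per frame from the state's von Mises distribution; iid Gaussian noise
    of width ``noise_sigma`` is added to every coordinate except (a) the
    designed correlation pairs, which receive residue-level correlated
    noise of the same width, and (b) the four atoms defining each designed
    psi angle, whose noise is the angular von Mises resampling itself.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    closed_ref, open_ref = make_two_lobe_model(cfg)
    s = closed_ref
    F = cfg.n_frames
    A = s.n_atoms
    labels = (np.arange(F) >= cfg.transition_frame).astype(int)
    refs = (closed_ref.coords, open_ref.coords)

    res_members = {resid: [i for i, a in enumerate(s.atoms) if a.resid == resid]
                   for resid in set(a.resid for a in s.atoms)}

    coords = np.empty((F, A, 3))
    psi_targets = {
        ds.resid: np.where(
            labels == 0,
            rng.vonmises(np.radians(ds.closed_psi), ds.kappa, F),
            rng.vonmises(np.radians(ds.open_psi), ds.kappa, F),
        )
        for ds in cfg.dihedral_shifts
    }
    # pre-draw correlated residue noise
    corr_noise: dict[int, np.ndarray] = {}
    for cp in cfg.correlation_pairs:
        a_noise = rng.standard_normal((F, 3))
        b_extra = rng.standard_normal((F, 3))
        sgn = np.where(labels == 0, 1.0, -1.0)[:, None]
        b_noise = cp.rho * sgn * a_noise + np.sqrt(1 - cp.rho ** 2) * b_extra
        corr_noise[cp.res_a] = cfg.noise_sigma * a_noise
        corr_noise[cp.res_b] = cfg.noise_sigma * b_noise

    # shared per-lobe rigid-body displacement (semi-rigid domain motion);
    # designed correlation/psi atoms keep their own noise models
    lobe_noise = cfg.lobe_noise_sigma * rng.standard_normal((F, 2, 3))
    n = cfg.n_residues_per_lobe
    lobe_of_atom = np.array([0 if a.resid <= n else 1 for a in s.atoms])

    # the designed psi series must follow the state's von Mises law, so the
    # four defining atoms carry that angular noise in place of Cartesian noise
    psi_exempt: list[int] = []
    for ds in cfg.dihedral_shifts:
        for resid, name in ((ds.resid, "N"), (ds.resid, "CA"), (ds.resid, "C"),
                            (ds.resid + 1, "N")):
            idx = s.find_atom(resid, name)
            if idx is not None:
                psi_exempt.append(idx)

    for t in range(F):
        frame = refs[labels[t]].copy()
        for ds in cfg.dihedral_shifts:
            _set_psi(frame, s, ds.resid, float(np.degrees(psi_targets[ds.resid][t])))
        noise = rng.standard_normal((A, 3)) * cfg.noise_sigma
        noise += lobe_noise[t, lobe_of_atom]
        for resid, nvec in corr_noise.items():
            noise[res_members[resid]] = nvec[t]
        noise[psi_exempt] = 0.0
        coords[t] = frame + noise

    traj = Trajectory(coords, np.arange(F, dtype=float), s)

    hinge_point, hinge_dir = _hinge_geometry(cfg)
    truth = GroundTruth(
        labels=StateLabels(labels, "ground-truth", int(cfg.transition_frame)),
        hinge=HingeResult(hinge_point, hinge_dir, float(cfg.theta), 0.0),
        designed_attribute_ids=(
            [f"contact:{p.res_a}-{p.res_b}" for p in cfg.contact_pairs]
            + [f"psi:{d.resid}" for d in cfg.dihedral_shifts]
            + [f"rcc:{c.res_a}-{c.res_b}" for c in cfg.correlation_pairs]
        ),
        lobe_assignment={
            resid: ("N-lobe" if resid <= cfg.n_residues_per_lobe else "C-lobe")
            for resid in res_members
        },
        contact_pairs=cfg.contact_pairs,
        dihedral_shifts=cfg.dihedral_shifts,
        correlation_pairs=cfg.correlation_pairs,
    )
    return traj, truth
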