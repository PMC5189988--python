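"""Per-frame structural attribute extraction.

Superposition (Kabsch), RMSF, distances, backbone dihedrals, Shrake-Rupley
SASA, geometric hydrogen bonds (3.2 A / 20 deg defaults), salt bridges
(3.5 A default), radius of gyration and maximum particle dimension.

Hydrogen-bond geometry is hydrogen-based by default; crystal structures
without hydrogens must either enable the heavy-atom fallback criterion or a
:class:`~mdstates.core.CapabilityError` is raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree, ConvexHull
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .core import AtomSelection, AttributeSeries, CapabilityError, Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "superpose",
    "apply_superposition",
    "fit_trajectory",
    "rmsf",
    "distance_series",
    "dihedral",
    "backbone_dihedrals",
    "sasa",
    "detect_hbonds",
    "detect_salt_bridges",
    "hbond_series",
    "saltbridge_series",
    "sasa_series",
    "contact_series",
    "radius_of_gyration",
    "max_dimension",
]


# --------------------------------------------------------------------------
# superposition

@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference:
    ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid-body superposition (Kabsch) of two point sets.

    Both sets must contain the same number (>= 3) of corresponding points.
    A proper rotation is always returned; degenerate (e.g. collinear)
    geometry yields a best-effort result with ``degenerate=True``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("point-count mismatch between mobile and reference")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 points of shape (N, 3)")
    if weights is None:
        w = np.ones(mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (mobile.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mc = (w[:, None] * mobile).sum(0) / wsum
    rc = (w[:, None] * reference).sum(0) / wsum
    degenerate = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc, weights=w)
    if any("unique" in str(c.message).lower() or "poorly defined" in str(c.message)
           for c in caught):
        degenerate = True
        warnings.warn("degenerate geometry: superposition is not unique")
    R = rot.as_matrix()
    t = rc - R @ mc
    rmsd = float(rssd / np.sqrt(wsum))
    return SuperpositionResult(R, t, rmsd, degenerate)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return coords @ result.rotation.T + result.translation


def fit_trajectory(
    traj: Trajectory,
    sel: AtomSelection,
    ref_frame: int = 0,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Remove global translation/rotation by least-squares fitting every
    frame to ``ref_frame`` over the selection; all atoms are transformed."""
    sel.validate(traj.topology)
    ref = traj.coords[ref_frame][sel.indices]
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        res = superpose(traj.coords[f][sel.indices], ref, weights)
        out[f] = apply_superposition(traj.coords[f], res)
    return Trajectory(out, traj.times.copy(), traj.topology)


def rmsf(traj: Trajectory, sel: AtomSelection) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    The trajectory is assumed to be already fitted to a reference frame
    (not detectable from the data; see :func:`fit_trajectory`).
    """
    sel.validate(traj.topology)
    x = traj.coords[:, sel.indices]
    dev = x - x.mean(axis=0)
    return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))


# --------------------------------------------------------------------------
# simple per-frame series

def distance_series(traj: Trajectory, i: int, j: int, stride: int = 1) -> AttributeSeries:
    """Euclidean distance between atoms ``i`` and ``j`` per (strided) frame."""
    A = traj.n_atoms
    if not (0 <= i < A and 0 <= j < A):
        raise IndexError("atom index out of range")
    if i == j:
        warnings.warn("distance_series called with i == j: all zeros")
    frames = np.arange(0, traj.n_frames, stride)
    d = np.linalg.norm(traj.coords[frames, i] - traj.coords[frames, j], axis=1)
    ai, aj = traj.topology.atoms[i], traj.topology.atoms[j]
    ident = f"distance:{ai.chain}{ai.resid}.{ai.name}-{aj.chain}{aj.resid}.{aj.name}"
    return AttributeSeries(ident, "distance", d, frames)


def contact_series(
    traj: Trajectory, i: int, j: int, cutoff: float = 6.0, stride: int = 1
) -> AttributeSeries:
    """Binary contact indicator: 1 when the i-j distance is <= cutoff."""
    d = distance_series(traj, i, j, stride)
    return AttributeSeries(
        d.id.replace("distance:", f"contact[{cutoff:g}A]:"),
        "contact",
        (d.values <= cutoff).astype(float),
        d.frame_index,
    )


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle(s) in degrees, range (-180, 180].

    Accepts single points or stacked ``(F, 3)`` arrays.
    """
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 onto +180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def backbone_dihedrals(
    traj: Trajectory,
    resid: int,
    chain: str | None = None,
    stride: int = 1,
) -> tuple[AttributeSeries | None, AttributeSeries | None]:
    """Phi/Psi time series of one residue, degrees in (-180, 180].

    Chain-terminal residues missing the neighbouring C or N return ``None``
    for the undefined angle.
    """
    top = traj.topology
    idx = {nm: top.find_atom(resid, nm, chain) for nm in ("N", "CA", "C")}
    if any(v is None for v in idx.values()):
        raise ValueError(f"residue {resid} lacks backbone atoms N/CA/C")
    c_prev = top.find_atom(resid - 1, "C", chain)
    n_next = top.find_atom(resid + 1, "N", chain)
    frames = np.arange(0, traj.n_frames, stride)
    x = traj.coords[frames]
    phi = psi = None
    if c_prev is not None:
        vals = dihedral(x[:, c_prev], x[:, idx["N"]], x[:, idx["CA"]], x[:, idx["C"]])
        phi = AttributeSeries(f"phi:{resid}", "phi", vals, frames)
    if n_next is not None:
        vals = dihedral(x[:, idx["N"]], x[:, idx["CA"]], x[:, idx["C"]], x[:, n_next])
        psi = AttributeSeries(f"psi:{resid}", "psi", vals, frames)
    return phi, psi


# --------------------------------------------------------------------------
# SASA (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's sphere of radius ``r_i + probe`` is sampled at ``n_points``
    quasi-uniform points; the unoccluded fraction is scaled to the sphere
    area.  Returns ``(per_atom, total)`` in A^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if np.any(radii <= 0):
        raise ValueError("atomic radii must be positive")
    if n_points < 32:
        warnings.warn("n_points < 32 gives poor SASA precision")
    n = coords.shape[0]
    ext = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    per_atom = np.empty(n)
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        nbrs = [j for j in tree.query_ball_point(coords[i], ext[i] + ext.max()) if j != i]
        nbrs = [j for j in nbrs if np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        if nbrs:
            d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(-1)
            thresh = (ext[nbrs] ** 2)[None, :]
            strictly_inside = d2 < thresh * (1.0 - 1e-9)
            # points exactly on a coincident neighbour's sphere: count the
            # surface once, keeping the lower-index atom's points exposed
            on_boundary = d2 <= thresh * (1.0 + 1e-9)
            tie = on_boundary & (np.asarray(nbrs)[None, :] < i)
            buried = (strictly_inside | tie).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return per_atom, float(per_atom.sum())


# --------------------------------------------------------------------------
# hydrogen bonds and salt bridges

#: Per-residue donor heavy atoms and acceptor atoms (backbone entries are
#: added for every standard residue).  Swappable via function arguments.
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("OD1",), "GLN": ("OE1",), "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"), "HIS": ("ND1", "NE2"), "MET": ("SD",),
}
_BACKBONE_DONOR = "N"
_BACKBONE_ACCEPTORS = ("O", "OXT")

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}

_H_BOND_MAX = 1.25  # A; covalent D-H detection


def _donor_acceptor_indices(s: Structure):
    donors, acceptors = [], []
    for i, a in enumerate(s.atoms):
        nm = a.name.strip()
        rn = a.resname.strip().upper()
        if nm == _BACKBONE_DONOR and rn != "PRO":
            donors.append(i)
        elif nm in SIDECHAIN_DONORS.get(rn, ()):
            donors.append(i)
        if nm in _BACKBONE_ACCEPTORS or nm in SIDECHAIN_ACCEPTORS.get(rn, ()):
            acceptors.append(i)
    return donors, acceptors


def _attached_hydrogens(s: Structure, coords: np.ndarray, donor: int) -> list[int]:
    da = s.atoms[donor]
    out = []
    for j, a in enumerate(s.atoms):
        if a.element == "H" and a.resid == da.resid and a.chain == da.chain:
            if np.linalg.norm(coords[j] - coords[donor]) <= _H_BOND_MAX:
                out.append(j)
    return out


def _antecedent(s: Structure, coords: np.ndarray, donor: int) -> int | None:
    """Heavy atom covalently bonded to the donor (nearest within 1.8 A)."""
    da = s.atoms[donor]
    best, bestd = None, 1.8
    for j, a in enumerate(s.atoms):
        if j == donor or a.element == "H":
            continue
        d = float(np.linalg.norm(coords[j] - coords[donor]))
        if d < bestd:
            best, bestd = j, d
    return best


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    s: Structure,
    coords: np.ndarray | None = None,
    d_cut: float = 3.2,
    a_cut: float = 20.0,
    require_hydrogens: bool = True,
) -> set[tuple[int, int | None, int]]:
    """Geometric hydrogen-bond detection on one frame.

    A (donor, hydrogen, acceptor) triple is reported iff the donor-acceptor
    distance is <= ``d_cut`` and the D-H...A angle is within ``a_cut`` of
    linear (>= 180 - a_cut).  With ``require_hydrogens=False`` a heavy-atom
    fallback variant is applied instead (D...A <= d_cut plus an
    antecedent-D-A angle >= 90 deg); its triples carry ``None`` hydrogens.
    Intra-residue pairs are excluded.
    """
    coords = s.coords if coords is None else np.asarray(coords, dtype=float)
    donors, acceptors = _donor_acceptor_indices(s)
    has_h = any(a.element == "H" for a in s.atoms)
    if require_hydrogens and not has_h:
        raise CapabilityError(
            "structure has no hydrogens; enable require_hydrogens=False for the "
            "heavy-atom fallback criterion"
        )
    use_h = has_h and require_hydrogens
    out: set[tuple[int, int | None, int]] = set()
    acc_tree = cKDTree(coords[acceptors]) if acceptors else None
    if acc_tree is None:
        return out
    for d in donors:
        da = s.atoms[d]
        near = acc_tree.query_ball_point(coords[d], d_cut)
        cand = [acceptors[k] for k in near]
        cand = [
            a for a in cand
            if not (s.atoms[a].resid == da.resid and s.atoms[a].chain == da.chain)
        ]
        if not cand:
            continue
        if use_h:
            for h in _attached_hydrogens(s, coords, d):
                for a in cand:
                    if _angle_deg(coords[d], coords[h], coords[a]) >= 180.0 - a_cut:
                        out.add((d, h, a))
        else:
            ante = _antecedent(s, coords, d)
            for a in cand:
                if ante is None or _angle_deg(coords[ante], coords[d], coords[a]) >= 90.0:
                    out.add((d, None, a))
    return out


def detect_salt_bridges(
    s: Structure,
    coords: np.ndarray | None = None,
    d_cut: float = 3.5,
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Salt bridges on one frame: ((acidic chain, resid), (basic chain, resid))
    pairs with any carboxylate O of Asp/Glu within ``d_cut`` of any
    side-chain N of Lys/Arg/His."""
    coords = s.coords if coords is None else np.asarray(coords, dtype=float)
    acid, base = [], []
    for i, a in enumerate(s.atoms):
        rn = a.resname.strip().upper()
        nm = a.name.strip()
        if nm in ACIDIC_ATOMS.get(rn, ()):
            acid.append(i)
        elif nm in BASIC_ATOMS.get(rn, ()):
            base.append(i)
    out: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    if not acid or not base:
        return out
    tree = cKDTree(coords[base])
    for i in acid:
        for k in tree.query_ball_point(coords[i], d_cut):
            j = base[k]
            out.add(
                (
                    (s.atoms[i].chain, s.atoms[i].resid),
                    (s.atoms[j].chain, s.atoms[j].resid),
                )
            )
    return out


def _pair_id(s: Structure, d: int, a: int) -> tuple:
    ad, aa = s.atoms[d], s.atoms[a]
    return (ad.chain, ad.resid, ad.name, aa.chain, aa.resid, aa.name)


def hbond_series(
    traj: Trajectory,
    stride: int = 25,
    d_cut: float = 3.2,
    a_cut: float = 20.0,
    require_hydrogens: bool = True,
) -> list[AttributeSeries]:
    """Binary presence series for every donor/acceptor pair observed in any
    strided frame.  Default stride of 25 frames mirrors a 25-ps cadence on a
    1-ps trajectory."""
    top = traj.topology
    frames = np.arange(0, traj.n_frames, stride)
    observed: dict[tuple, np.ndarray] = {}
    for k, f in enumerate(frames):
        found = detect_hbonds(top, traj.coords[f], d_cut, a_cut, require_hydrogens)
        for d, _, a in found:
            key = _pair_id(top, d, a)
            if key not in observed:
                observed[key] = np.zeros(frames.size)
            observed[key][k] = 1.0
    out = []
    for key, vals in sorted(observed.items()):
        ident = f"hbond:{key[0]}{key[1]}.{key[2]}-{key[3]}{key[4]}.{key[5]}"
        out.append(AttributeSeries(ident, "hbond", vals, frames))
    return out


def saltbridge_series(
    traj: Trajectory, stride: int = 25, d_cut: float = 3.5
) -> list[AttributeSeries]:
    top = traj.topology
    frames = np.arange(0, traj.n_frames, stride)
    observed: dict[tuple, np.ndarray] = {}
    for k, f in enumerate(frames):
        for pair in detect_salt_bridges(top, traj.coords[f], d_cut):
            if pair not in observed:
                observed[pair] = np.zeros(frames.size)
            observed[pair][k] = 1.0
    out = []
    for (ac, bs), vals in sorted(observed.items()):
        ident = f"saltbridge:{ac[0]}{ac[1]}-{bs[0]}{bs[1]}"
        out.append(AttributeSeries(ident, "saltbridge", vals, frames))
    return out


def sasa_series(
    traj: Trajectory,
    resids: list[int] | None = None,
    stride: int = 25,
    probe: float = 1.4,
    n_points: int = 240,
) -> list[AttributeSeries]:
    """Per-residue SASA time series (sum over the residue's atoms)."""
    top = traj.topology
    frames = np.arange(0, traj.n_frames, stride)
    radii = top.radii
    groups = [
        (key, idx) for key, idx in top.residues()
        if resids is None or key[1] in resids
    ]
    per_res = {key: np.zeros(frames.size) for key, _ in groups}
    for k, f in enumerate(frames):
        atom_area, _ = sasa(traj.coords[f], radii, probe=probe, n_points=n_points)
        for key, idx in groups:
            per_res[key][k] = atom_area[idx].sum()
    return [
        AttributeSeries(f"sasa:{key[0]}{key[1]}", "sasa", vals, frames)
        for (key, vals) in ((key, per_res[key]) for key, _ in groups)
    ]


# --------------------------------------------------------------------------
# global shape descriptors

def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration about the centre of mass (A)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    m = np.ones(coords.shape[0]) if masses is None else np.asarray(masses, float)
    com = (m[:, None] * coords).sum(0) / m.sum()
    return float(np.sqrt((m * ((coords - com) ** 2).sum(1)).sum() / m.sum()))


def max_dimension(coords: np.ndarray) -> float:
    """Maximum pairwise interatomic distance (A).

    Exact for <= 10^4 points; above that the convex hull vertices (which
    contain the diameter endpoints) are enumerated instead.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least two atoms")
    pts = coords
    if coords.shape[0] > 10_000:
        pts = coords[ConvexHull(coords).vertices]
    return float(pdist(pts).max())
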