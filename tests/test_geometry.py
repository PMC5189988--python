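"""Superposition, RMSF, dihedrals, SASA, H-bonds, salt bridges, Rg, Dmax."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdstates.core import CapabilityError
from mdstates.geometry import (
    backbone_dihedrals,
    detect_hbonds,
    detect_salt_bridges,
    dihedral,
    distance_series,
    max_dimension,
    radius_of_gyration,
    rmsf,
    sasa,
    superpose,
)
from mdstates.selections import select

from conftest import make_structure, make_trajectory


# --------------------------------------------------------------------------
# superposition

def _random_points(n, seed):
    return np.random.default_rng(seed).normal(0, 3, (n, 3))


def test_superpose_identical_sets():
    pts = _random_points(6, 0)
    res = superpose(pts, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-6)


def test_superpose_pure_rotation():
    pts = _random_points(8, 1)
    rot = Rotation.from_euler("z", 90, degrees=True)
    res = superpose(rot.apply(pts), pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-8)


def _grid_rmsd(mc, rc, centres, span, steps):
    grids = [
        np.array(list(itertools.product(*(np.linspace(c - span, c + span, steps)
                                          for c in centre))))
        for centre in centres
    ]
    angles = np.vstack(grids)
    M = Rotation.from_euler("xyz", angles).as_matrix()
    rotated = np.einsum("nij,kj->nki", M, mc)
    rmsds = np.sqrt(((rc[None] - rotated) ** 2).sum(axis=2).mean(axis=1))
    return angles, rmsds


def _brute_force_rmsd(mobile, reference, rounds=4, steps=11, n_starts=8):
    """Independent oracle: multi-start nested grid search over Euler angles."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    angles, rmsds = _grid_rmsd(mc, rc, [np.zeros(3)], np.pi, 19)
    order = np.argsort(rmsds)[:n_starts]
    centres = [angles[i] for i in order]
    best = rmsds.min()
    span = np.pi / 9
    for _ in range(rounds):
        angles, rmsds = _grid_rmsd(mc, rc, centres, span, steps)
        order = np.argsort(rmsds)[:n_starts]
        centres = [angles[i] for i in order]
        best = min(best, rmsds.min())
        span /= (steps - 1) / 2
    return float(best)


def test_superpose_matches_rotation_grid_search():
    mobile = _random_points(5, 2)
    reference = _random_points(5, 3)
    res = superpose(mobile, reference)
    assert res.rmsd == pytest.approx(_brute_force_rmsd(mobile, reference), abs=1e-3)


def test_superpose_symmetric_rmsd():
    a = _random_points(7, 4)
    b = _random_points(7, 5)
    assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd, abs=1e-8)


def test_superpose_mismatch_and_degenerate():
    with pytest.raises(ValueError):
        superpose(_random_points(5, 0), _random_points(6, 0))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.warns(UserWarning, match="degenerate"):
        res = superpose(line, line + 1.0)
    assert res.degenerate


# --------------------------------------------------------------------------
# RMSF / distances

def _one_atom_traj(frames):
    s = make_structure([("CA", "ALA", 1, (0, 0, 0)), ("CA", "ALA", 2, (5, 0, 0))])
    return make_trajectory(s, frames)


def test_rmsf_static_is_zero(tripeptide):
    traj = make_trajectory(tripeptide, np.stack([tripeptide.coords] * 4))
    sel = select(tripeptide, "name CA")
    np.testing.assert_allclose(rmsf(traj, sel), 0.0, atol=1e-12)


def test_rmsf_oscillation_closed_form():
    d = 0.7
    frames = np.zeros((4, 2, 3))
    frames[:, 1, 0] = 5.0
    frames[[0, 2], 0, 0] = d
    frames[[1, 3], 0, 0] = -d
    traj = _one_atom_traj(frames)
    sel = select(traj.topology, "name CA")
    out = rmsf(traj, sel)
    assert out[0] == pytest.approx(d)
    assert out[1] == pytest.approx(0.0, abs=1e-12)


def test_rmsf_mobile_lobe_exceeds_static_lobe(fitted_ca):
    fitted, sel, truth = fitted_ca
    vals = rmsf(fitted, sel)
    resids = np.array([fitted.topology.atoms[i].resid for i in sel.indices])
    lobes = np.array([truth.lobe_assignment[r] for r in resids])
    assert vals[lobes == "C-lobe"].mean() > vals[lobes == "N-lobe"].mean()


def test_distance_series_constant_and_step():
    frames = np.zeros((6, 2, 3))
    frames[:, 1, 0] = 3.0
    frames[3:, 1, 0] = 10.0
    traj = _one_atom_traj(frames)
    d = distance_series(traj, 0, 1)
    np.testing.assert_allclose(d.values[:3], 3.0)
    np.testing.assert_allclose(d.values[3:], 10.0)


def test_distance_series_same_atom_warns():
    traj = _one_atom_traj(np.zeros((3, 2, 3)))
    with pytest.warns(UserWarning):
        d = distance_series(traj, 0, 0)
    np.testing.assert_allclose(d.values, 0.0)


# --------------------------------------------------------------------------
# dihedrals

def test_dihedral_planar_trans():
    ang = dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0))
    assert float(ang) == pytest.approx(180.0)


def test_dihedral_mirror_flips_sign():
    pts = np.array([[0, 0, 0], [1.5, 0, 0], [2.0, 1.4, 0], [3.1, 1.7, 1.1]], dtype=float)
    ang = float(dihedral(*pts))
    mirrored = pts * np.array([1, 1, -1])
    assert float(dihedral(*mirrored)) == pytest.approx(-ang)


def _dihedral_oracle(p0, p1, p2, p3):
    """Independent two-plane atan2 evaluation (IUPAC sign convention,
    cross-checked against MDAnalysis.lib.distances.calc_dihedrals)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return -np.degrees(np.arctan2(m1 @ n2, n1 @ n2))


@pytest.mark.parametrize("seed", range(5))
def test_dihedral_matches_independent_formula(seed):
    pts = np.random.default_rng(seed).normal(0, 2, (4, 3))
    expected = _dihedral_oracle(*pts)
    assert float(dihedral(*pts)) == pytest.approx(expected, abs=1e-9)


def test_backbone_dihedrals_terminal_markers(tripeptide):
    traj = make_trajectory(tripeptide, np.stack([tripeptide.coords] * 2))
    phi, psi = backbone_dihedrals(traj, 1)
    assert phi is None and psi is not None
    phi, psi = backbone_dihedrals(traj, 3)
    assert phi is not None and psi is None
    phi, psi = backbone_dihedrals(traj, 2)
    assert -180.0 < float(psi.values[0]) <= 180.0


# --------------------------------------------------------------------------
# SASA

def test_sasa_isolated_atom_analytic():
    r = 1.9
    per_atom, total = sasa(np.zeros((1, 3)), np.array([r]), probe=1.4, n_points=960)
    expected = 4 * np.pi * (r + 1.4) ** 2
    assert total == pytest.approx(expected, rel=0.01)


def test_sasa_coincident_atoms():
    coords = np.zeros((2, 3))
    radii = np.array([1.7, 1.7])
    _, total = sasa(coords, radii, n_points=960)
    expected = 4 * np.pi * (1.7 + 1.4) ** 2
    assert total == pytest.approx(expected, rel=0.01)


def test_sasa_cluster_matches_dense_grid_oracle():
    rng = np.random.default_rng(0)
    coords = rng.normal(0, 1.5, (5, 3))
    radii = np.full(5, 1.7)
    _, fast = sasa(coords, radii, n_points=960)
    _, dense = sasa(coords, radii, n_points=100_000)
    assert fast == pytest.approx(dense, rel=0.02)


def test_sasa_occlusion_monotonic():
    rng = np.random.default_rng(3)
    coords = rng.normal(0, 2.0, (6, 3))
    radii = np.full(6, 1.6)
    before, _ = sasa(coords, radii, n_points=960)
    coords2 = np.vstack([coords, coords.mean(axis=0)])
    after, _ = sasa(coords2, np.full(7, 1.6), n_points=960)
    assert after[:6].sum() <= before.sum() + 1e-9


def test_sasa_low_point_warning():
    with pytest.warns(UserWarning, match="precision"):
        sasa(np.zeros((1, 3)), np.array([1.5]), n_points=16)


# --------------------------------------------------------------------------
# hydrogen bonds

def _hbond_fixture(no_distance=2.9, dha_angle=180.0):
    """Backbone N-H donor of residue 1 aimed at the O acceptor of residue 5."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    # place O so that N...O = no_distance and angle D-H-A = dha_angle
    theta = np.radians(180.0 - dha_angle)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # solve |n + t*unit_from_h - ...|: construct acceptor along direction from H
    # distance H->A chosen so that |N-A| = no_distance
    # |h + s*direction - n| = no_distance
    b = 2 * (h - n) @ direction
    c = (h - n) @ (h - n) - no_distance ** 2
    s = (-b + np.sqrt(b * b - 4 * c)) / 2
    o = h + s * direction
    return make_structure(
        [
            ("N", "ALA", 1, n),
            ("H", "ALA", 1, h),
            ("CA", "ALA", 1, (0.5, 1.4, 0.0)),
            ("O", "ALA", 5, o),
        ]
    )


def test_hbond_linear_within_cutoffs_detected():
    s = _hbond_fixture(2.9, 180.0)
    found = detect_hbonds(s)
    assert any(s.atoms[d].name == "N" and s.atoms[a].name == "O" for d, _, a in found)


def test_hbond_distance_cutoff_rejects():
    assert detect_hbonds(_hbond_fixture(3.3, 180.0)) == set()


def test_hbond_angle_cutoff_rejects():
    assert detect_hbonds(_hbond_fixture(2.9, 150.0)) == set()


def test_hbond_requires_hydrogens():
    s = make_structure([("N", "ALA", 1, (0, 0, 0)), ("O", "ALA", 5, (2.9, 0, 0))])
    with pytest.raises(CapabilityError):
        detect_hbonds(s)
    assert len(detect_hbonds(s, require_hydrogens=False)) >= 0  # fallback runs


def _brute_force_hbonds(s, d_cut=3.2, a_cut=20.0):
    """Independent enumeration over all donor/H/acceptor triples."""
    from mdstates.geometry import (
        SIDECHAIN_ACCEPTORS,
        SIDECHAIN_DONORS,
        _angle_deg,
    )

    coords = s.coords
    out = set()
    for d, ad in enumerate(s.atoms):
        rn = ad.resname.upper()
        is_donor = (ad.name == "N" and rn != "PRO") or ad.name in SIDECHAIN_DONORS.get(rn, ())
        if not is_donor:
            continue
        for h, ah in enumerate(s.atoms):
            if ah.element != "H" or ah.resid != ad.resid or ah.chain != ad.chain:
                continue
            if np.linalg.norm(coords[h] - coords[d]) > 1.25:
                continue
            for a, aa in enumerate(s.atoms):
                rn_a = aa.resname.upper()
                is_acc = aa.name in ("O", "OXT") or aa.name in SIDECHAIN_ACCEPTORS.get(rn_a, ())
                if not is_acc:
                    continue
                if aa.resid == ad.resid and aa.chain == ad.chain:
                    continue
                if np.linalg.norm(coords[a] - coords[d]) > d_cut:
                    continue
                if _angle_deg(coords[d], coords[h], coords[a]) >= 180 - a_cut:
                    out.add((d, h, a))
    return out


def test_hbond_detection_equals_brute_force():
    rng = np.random.default_rng(7)
    spec = []
    for r in range(8):
        base = rng.normal(0, 2.5, 3)
        spec += [
            ("N", "ALA", r + 1, base),
            ("H", "ALA", r + 1, base + [1.0, 0, 0]),
            ("O", "ALA", r + 1, base + rng.normal(0, 1.5, 3)),
        ]
    s = make_structure(spec)
    assert detect_hbonds(s) == _brute_force_hbonds(s)


# --------------------------------------------------------------------------
# salt bridges

def _salt_fixture(dist):
    return make_structure(
        [
            ("OD1", "ASP", 10, (0, 0, 0)),
            ("OD2", "ASP", 10, (-0.8, 1.0, 0)),
            ("CB", "ASP", 10, (-0.8, -1.0, 0)),
            ("NZ", "LYS", 20, (dist, 0, 0)),
        ]
    )


def test_salt_bridge_within_cutoff():
    assert detect_salt_bridges(_salt_fixture(3.4)) == {(("A", 10), ("A", 20))}


def test_salt_bridge_beyond_cutoff():
    assert detect_salt_bridges(_salt_fixture(3.6)) == set()


def test_salt_bridge_needs_basic_partner():
    s = make_structure(
        [
            ("OD1", "ASP", 10, (0, 0, 0)),
            ("OD1", "ASP", 11, (3.0, 0, 0)),
        ]
    )
    assert detect_salt_bridges(s) == set()


def test_salt_bridge_equals_brute_force():
    rng = np.random.default_rng(11)
    spec = []
    names = [("OD1", "ASP"), ("OE1", "GLU"), ("NZ", "LYS"), ("NH1", "ARG"), ("NE2", "HIS")]
    for r in range(12):
        nm, rn = names[r % len(names)]
        spec.append((nm, rn, r + 1, rng.normal(0, 3.0, 3)))
    s = make_structure(spec)
    coords = s.coords
    from mdstates.geometry import ACIDIC_ATOMS, BASIC_ATOMS

    expected = set()
    for i, ai in enumerate(s.atoms):
        for j, aj in enumerate(s.atoms):
            if ai.name in ACIDIC_ATOMS.get(ai.resname, ()) and aj.name in BASIC_ATOMS.get(aj.resname, ()):
                if np.linalg.norm(coords[i] - coords[j]) <= 3.5:
                    expected.add(((ai.chain, ai.resid), (aj.chain, aj.resid)))
    assert detect_salt_bridges(s) == expected


# --------------------------------------------------------------------------
# Rg / Dmax

def test_rg_single_atom_zero():
    assert radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0


def test_rg_two_unit_masses():
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    assert radius_of_gyration(coords, np.ones(2)) == pytest.approx(1.0)


def test_dmax_two_points_and_cube():
    assert max_dimension(np.array([[0.0, 0, 0], [5.0, 0, 0]])) == pytest.approx(5.0)
    cube = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
    assert max_dimension(cube) == pytest.approx(np.sqrt(3))


@pytest.mark.parametrize("seed", [0, 1])
def test_rg_dmax_rigid_motion_invariant(seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(0, 5, (40, 3))
    masses = rng.uniform(1, 16, 40)
    rot = Rotation.random(random_state=seed)
    moved = rot.apply(coords) + rng.normal(0, 10, 3)
    assert radius_of_gyration(moved, masses) == pytest.approx(
        radius_of_gyration(coords, masses), abs=1e-8
    )
    assert max_dimension(moved) == pytest.approx(max_dimension(coords), abs=1e-8)
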