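"""PCA, k-means states, distance assignment, landscapes, hinge axis."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdstates.core import AtomSelection, AttributeSeries
from mdstates.selections import select
from mdstates.states import (
    assign_states_by_distance,
    fit_pca,
    free_energy_landscape,
    hinge_axis,
    kmeans_states,
    project,
)

from conftest import make_structure, make_trajectory


def _toy_structure(n):
    return make_structure([("CA", "ALA", i + 1, (4.0 * i, 0, 0)) for i in range(n)])


def _sel(n):
    return AtomSelection(np.arange(n))


# --------------------------------------------------------------------------
# PCA

def test_pca_rank_one_motion():
    s = _toy_structure(3)
    frames = np.stack([s.coords] * 10)
    frames[:, 0, 0] += np.linspace(0, 2, 10)
    traj = make_trajectory(s, frames)
    model = fit_pca(traj, _sel(3), fit=False)
    assert model.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_static_trajectory():
    s = _toy_structure(3)
    traj = make_trajectory(s, np.stack([s.coords] * 5))
    model = fit_pca(traj, _sel(3), fit=False)
    np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-12)


def test_pca_matches_direct_covariance_oracle():
    rng = np.random.default_rng(0)
    s = _toy_structure(3)
    frames = np.stack([s.coords] * 10) + rng.normal(0, 1, (10, 3, 3))
    traj = make_trajectory(s, frames)
    model = fit_pca(traj, _sel(3), fit=False)
    # independent recomputation: explicit summation covariance + eigensolver
    X = frames.reshape(10, 9)
    mean = X.mean(axis=0)
    C = np.zeros((9, 9))
    for row in X:
        d = row - mean
        C += np.outer(d, d)
    C /= 9
    expected = np.sort(np.linalg.eigvalsh(C))[::-1]
    np.testing.assert_allclose(model.eigenvalues, expected, atol=1e-10)
    # conservation: eigenvalue sum equals total coordinate variance
    total_var = ((X - mean) ** 2).sum() / 9
    assert model.eigenvalues.sum() == pytest.approx(total_var, abs=1e-6)


def test_pca_orthonormal_and_sign_convention(fitted_ca):
    fitted, sel, _ = fitted_ca
    model = fit_pca(fitted, sel, fit=False)
    k = 5
    V = model.eigenvectors[:, :k]
    np.testing.assert_allclose(V.T @ V, np.eye(k), atol=1e-8)
    for j in range(k):
        assert V[np.abs(V[:, j]).argmax(), j] > 0


def test_project_identities():
    rng = np.random.default_rng(1)
    s = _toy_structure(4)
    frames = np.stack([s.coords] * 50) + rng.normal(0, 1, (50, 4, 3))
    traj = make_trajectory(s, frames)
    model = fit_pca(traj, _sel(4), fit=False)
    proj = project(traj, model, 6, fit=False)
    # column variance equals the eigenvalue
    np.testing.assert_allclose(proj.var(axis=0, ddof=1), model.eigenvalues[:6], atol=1e-8)
    # projecting the mean structure gives zeros
    mean_frames = np.stack([frames.mean(axis=0)] * 2)
    mean_traj = make_trajectory(s, mean_frames)
    np.testing.assert_allclose(project(mean_traj, model, 6, fit=False), 0.0, atol=1e-8)


def test_projection_bimodal_on_two_state_run(fitted_ca):
    fitted, sel, truth = fitted_ca
    model = fit_pca(fitted, sel, fit=False)
    pc1 = project(fitted, model, 1, fit=False)[:, 0]
    lab = truth.labels.labels
    m0, m1 = pc1[lab == 0].mean(), pc1[lab == 1].mean()
    pooled = np.sqrt(0.5 * (pc1[lab == 0].var() + pc1[lab == 1].var()))
    assert abs(m1 - m0) > 4 * pooled


# --------------------------------------------------------------------------
# k-means

def _two_gaussians(seed=0, n=500):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(-5, 0.5, n), rng.normal(5, 0.5, n)])
    labels = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return x[:, None], labels


def test_kmeans_single_cluster_bss_zero():
    X, _ = _two_gaussians()
    _, bss = kmeans_states(X, n_clusters=1)
    assert bss == 0.0


def test_kmeans_two_gaussians_accuracy():
    X, truth = _two_gaussians()
    labels, bss = kmeans_states(X, n_clusters=2, seed=0)
    acc = max((labels.labels == truth).mean(), (labels.labels == 1 - truth).mean())
    assert acc >= 0.99
    assert bss >= 0.95


def test_kmeans_elbow_at_two():
    X, _ = _two_gaussians()
    scores = [kmeans_states(X, n_clusters=k, seed=0)[1] for k in range(1, 7)]
    gains = np.diff(scores)
    assert int(np.argmax(gains)) == 0  # the k=1 -> k=2 step


@pytest.mark.parametrize("seed", range(5))
def test_kmeans_deterministic_and_robust(seed):
    X, truth = _two_gaussians(seed=seed)
    a, _ = kmeans_states(X, n_clusters=2, seed=seed)
    b, _ = kmeans_states(X, n_clusters=2, seed=seed)
    np.testing.assert_array_equal(a.labels, b.labels)
    acc = max((a.labels == truth).mean(), (a.labels == 1 - truth).mean())
    assert acc >= 0.99


def test_kmeans_label_zero_contains_frame_zero(fitted_ca):
    fitted, sel, truth = fitted_ca
    model = fit_pca(fitted, sel, fit=False)
    proj = project(fitted, model, 2, fit=False)
    labels, bss = kmeans_states(proj, 2, seed=0)
    assert labels.labels[0] == 0
    assert (labels.labels == truth.labels.labels).mean() >= 0.99


# --------------------------------------------------------------------------
# distance-threshold assignment

def test_assign_states_constant_no_transition():
    s = AttributeSeries("d", "distance", np.full(50, 3.0), np.arange(50))
    out = assign_states_by_distance(s, 4.0)
    assert out.labels.sum() == 0 and out.transition_frame is None


def test_assign_states_step_transition_frame():
    vals = np.where(np.arange(300) < 100, 3.0, 10.0)
    s = AttributeSeries("d", "distance", vals, np.arange(300))
    out = assign_states_by_distance(s, 4.0)
    assert out.transition_frame == 100


def test_assign_states_matches_ground_truth(default_sim):
    from mdstates.geometry import distance_series

    traj, truth = default_sim
    cp = truth.contact_pairs[0]
    top = traj.topology
    d = distance_series(traj, top.find_atom(cp.res_a, "CA"), top.find_atom(cp.res_b, "CA"))
    out = assign_states_by_distance(d, (cp.closed_distance + cp.open_distance) / 2)
    assert (out.labels == truth.labels.labels).mean() >= 0.98


# --------------------------------------------------------------------------
# free-energy landscape

def test_landscape_flat_for_uniform_samples():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 1, (25_000, 2))
    fel = free_energy_landscape(X, bins=5)
    assert fel.delta_g.min() == 0.0
    assert fel.delta_g.max() < np.log(2)


def test_landscape_single_point():
    X = np.zeros((100, 2))
    fel = free_energy_landscape(X, bins=10)
    occupied = np.isfinite(fel.delta_g)
    assert occupied.sum() == 1
    assert fel.delta_g[occupied][0] == 0.0


def test_landscape_two_minima_with_barrier():
    rng = np.random.default_rng(1)
    a = rng.normal([-4, 0], 0.5, (3000, 2))
    b = rng.normal([4, 0], 0.5, (3000, 2))
    fel = free_energy_landscape(np.vstack([a, b]), bins=40)
    assert fel.delta_g.min() == 0.0
    # the ridge between the two x-side minima is at least 1 kT high
    col_min = np.min(np.where(np.isfinite(fel.delta_g), fel.delta_g, np.inf), axis=1)
    left = col_min[: len(col_min) // 3].min()
    right = col_min[-len(col_min) // 3:].min()
    middle = col_min[len(col_min) // 3: -len(col_min) // 3].min()
    assert middle - max(left, right) >= 1.0


# --------------------------------------------------------------------------
# hinge axis

def _hinge_fixture(theta=20.0):
    rng = np.random.default_rng(0)
    fixed = rng.normal(0, 3, (10, 3)) + np.array([-8.0, 0, 0])
    mobile = rng.normal(0, 3, (10, 3)) + np.array([8.0, 0, 0])
    a = np.vstack([fixed, mobile])
    rot = Rotation.from_euler("z", theta, degrees=True)
    b = a.copy()
    b[10:] = rot.apply(a[10:])
    return a, b, AtomSelection(np.arange(10)), AtomSelection(np.arange(10, 20))


def test_hinge_constructed_rotation():
    a, b, fixed, mobile = _hinge_fixture(20.0)
    res = hinge_axis(a, b, fixed, mobile)
    assert res.defined
    assert res.angle == pytest.approx(20.0, abs=0.1)
    cosang = abs(res.axis_direction @ np.array([0, 0, 1.0]))
    assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 1.0


def test_hinge_identity_undefined():
    a, _, fixed, mobile = _hinge_fixture()
    res = hinge_axis(a, a, fixed, mobile)
    assert not res.defined


def test_hinge_invariant_under_global_motion():
    a, b, fixed, mobile = _hinge_fixture(25.0)
    res0 = hinge_axis(a, b, fixed, mobile)
    rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.2])
    shift = np.array([5.0, -3.0, 7.0])
    res1 = hinge_axis(rot.apply(a) + shift, rot.apply(b) + shift, fixed, mobile)
    assert res1.angle == pytest.approx(res0.angle, abs=0.1)


def test_hinge_recovers_generator_axis(default_sim):
    from mdstates.synthetic import GeneratorConfig, make_two_lobe_model

    cfg = GeneratorConfig(seed=1)
    closed, opened = make_two_lobe_model(cfg)
    _, truth = default_sim
    n = cfg.n_residues_per_lobe
    adjusted = {p.res_b for p in cfg.contact_pairs}
    top = closed
    fixed_idx = [i for i, a in enumerate(top.atoms)
                 if a.name == "CA" and a.resid <= n]
    mobile_idx = [i for i, a in enumerate(top.atoms)
                  if a.name == "CA" and a.resid > n and a.resid not in adjusted]
    res = hinge_axis(
        closed.coords, opened.coords,
        AtomSelection(np.array(fixed_idx)), AtomSelection(np.array(mobile_idx)),
    )
    assert res.angle == pytest.approx(cfg.theta, abs=0.5)
    cosang = abs(res.axis_direction @ truth.hinge.axis_direction)
    assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 1.0
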