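"""Conformational-state discovery.

Cartesian covariance PCA over a selection (typically Calpha atoms),
trajectory projection, k-means clustering of the projection with the
BSS/TSS elbow statistic, distance-threshold state assignment, PCA-based
free-energy landscapes, and screw-axis (hinge) decomposition of domain
motion between two conformers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from .core import AtomSelection, AttributeSeries, StateLabels, Trajectory, longest_run_start
from .geometry import apply_superposition, fit_trajectory, superpose

__all__ = [
    "PCAModel",
    "fit_pca",
    "project",
    "kmeans_states",
    "assign_states_by_distance",
    "FreeEnergyLandscape",
    "free_energy_landscape",
    "HingeResult",
    "hinge_axis",
]


@dataclass
class PCAModel:
    """Eigendecomposition of the 3N x 3N Cartesian covariance matrix."""

    mean: np.ndarray
    eigenvectors: np.ndarray  # (3N, m), orthonormal columns
    eigenvalues: np.ndarray  # descending, >= 0
    variance_fraction: np.ndarray
    selection: AtomSelection | None = None


def _flatten(traj: Trajectory, sel: AtomSelection) -> np.ndarray:
    return traj.coords[:, sel.indices].reshape(traj.n_frames, -1)


def fit_pca(
    traj: Trajectory,
    sel: AtomSelection,
    fit: bool = True,
    ref_frame: int = 0,
) -> PCAModel:
    """PCA of the selection's Cartesian coordinates.

    With ``fit=True`` (default) global motion is first removed by
    least-squares fitting every frame to ``ref_frame`` over the selection.
    Eigenvector signs follow a fixed convention: the largest-magnitude
    component of each eigenvector is made positive.
    """
    sel.validate(traj.topology)
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    work = fit_trajectory(traj, sel, ref_frame) if fit else traj
    X = _flatten(work, sel)
    n3 = X.shape[1]
    if traj.n_frames <= n3:
        warnings.warn(
            f"only {traj.n_frames} frames for {n3} coordinates: covariance is rank-deficient"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign convention
    flip = evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])] < 0
    evecs[:, flip] *= -1.0
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCAModel(mean, evecs, evals, frac, sel)


def project(
    traj: Trajectory,
    model: PCAModel,
    k: int,
    fit: bool = True,
    ref_frame: int = 0,
) -> np.ndarray:
    """Project (fitted) coordinates onto the first ``k`` eigenvectors."""
    if k > model.eigenvectors.shape[1]:
        raise ValueError("k exceeds the number of stored components")
    if model.selection is None:
        raise ValueError("model carries no selection")
    work = fit_trajectory(traj, model.selection, ref_frame) if fit else traj
    X = _flatten(work, model.selection)
    if X.shape[1] != model.mean.size:
        raise ValueError("selection/model dimensionality mismatch")
    return (X - model.mean) @ model.eigenvectors[:, :k]


def kmeans_states(
    projection: np.ndarray,
    n_clusters: int = 2,
    n_restarts: int = 25,
    seed: int = 0,
) -> tuple[StateLabels, float]:
    """k-means++ clustering of the PC projection.

    Returns labels (cluster containing frame 0 is relabelled 0, the closed
    start) and the BSS/TSS fraction 1 - WSS/TSS.  For two clusters the
    transition frame is the start of the longest open run.
    """
    X = np.asarray(projection, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    F = X.shape[0]
    if n_clusters < 1 or F <= n_clusters:
        raise ValueError("need F > n_clusters >= 1")
    if n_clusters == 1:
        return StateLabels(np.zeros(F, dtype=int), "kmeans-pc", None), 0.0
    km = KMeans(n_clusters=n_clusters, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    bss_tss = 1.0 - float(km.inertia_) / tss if tss > 0 else 0.0
    # relabel: cluster of frame 0 -> 0, remaining clusters by first appearance
    mapping = {int(raw[0]): 0}
    nxt = 1
    for c in raw:
        c = int(c)
        if c not in mapping:
            mapping[c] = nxt
            nxt += 1
    labels = np.array([mapping[int(c)] for c in raw])
    transition = None
    if n_clusters == 2 and labels.min() == 0 and labels.max() == 1:
        transition = longest_run_start(labels, 1)
    return StateLabels(labels, "kmeans-pc", transition), bss_tss


def assign_states_by_distance(series: AttributeSeries, threshold: float) -> StateLabels:
    """Open (1) where the distance exceeds the threshold.

    The transition frame is the first index of the longest open run; a
    single-label series is valid and carries no transition.
    """
    labels = (series.values > threshold).astype(int)
    if labels.min() == labels.max():
        return StateLabels(labels, "distance-threshold", None)
    return StateLabels(labels, "distance-threshold", longest_run_start(labels, 1))


@dataclass
class FreeEnergyLandscape:
    """-ln(rho/rho_max) over a 2-D histogram of the PC projection (kT units).

    Empty bins are +inf (unbounded), the global minimum is exactly 0."""

    delta_g: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    temperature: float


def free_energy_landscape(
    projection: np.ndarray,
    bins: int = 80,
    temperature: float = 300.0,
) -> FreeEnergyLandscape:
    X = np.asarray(projection, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("projection must be (F, >=2); the first two columns are used")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if X.shape[0] < bins:
        raise ValueError("need at least as many frames as bins")
    H, xe, ye = np.histogram2d(X[:, 0], X[:, 1], bins=bins)
    with np.errstate(divide="ignore"):
        dg = -np.log(H / H.max())
    dg[H == 0] = np.inf
    return FreeEnergyLandscape(dg, xe, ye, temperature)


@dataclass
class HingeResult:
    """Screw-axis decomposition of a mobile domain's motion between two
    conformers, after superposing the fixed domain."""

    axis_point: np.ndarray | None
    axis_direction: np.ndarray | None
    angle: float
    screw_translation: float
    defined: bool = True


def hinge_axis(
    conf_a: np.ndarray,
    conf_b: np.ndarray,
    domain_fixed: AtomSelection,
    domain_mobile: AtomSelection,
    min_angle: float = 1.0,
) -> HingeResult:
    """Hinge (screw) axis of the mobile domain between two conformations.

    ``conf_b`` is superposed onto ``conf_a`` over the fixed domain; the
    best rigid transform of the mobile domain between the aligned pair is
    decomposed into rotation angle, axis direction, a point on the axis
    (closest to the origin) and the translation along the axis.  Motion
    below ``min_angle`` degrees yields an undefined-axis flag.
    """
    conf_a = np.asarray(conf_a, dtype=float)
    conf_b = np.asarray(conf_b, dtype=float)
    if conf_a.shape != conf_b.shape:
        raise ValueError("conformer shapes differ")
    fi, mi = domain_fixed.indices, domain_mobile.indices
    if fi.size < 3 or mi.size < 3:
        raise ValueError("both domains need >= 3 atoms")
    if np.intersect1d(fi, mi).size:
        raise ValueError("fixed and mobile selections must be disjoint")
    aligned_b = apply_superposition(conf_b, superpose(conf_b[fi], conf_a[fi]))
    res = superpose(aligned_b[mi], conf_a[mi])
    rotvec = Rotation.from_matrix(res.rotation).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < min_angle:
        return HingeResult(None, None, angle, 0.0, defined=False)
    direction = rotvec / np.linalg.norm(rotvec)
    d_axial = float(direction @ res.translation)
    t_perp = res.translation - d_axial * direction
    # axis point p solves (I - R) p = t_perp; singular along the axis, so
    # take the minimum-norm solution (point on the axis closest to origin).
    point, *_ = np.linalg.lstsq(np.eye(3) - res.rotation, t_perp, rcond=None)
    point = point - (direction @ point) * direction
    return HingeResult(point, direction, angle, d_axial, defined=True)
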