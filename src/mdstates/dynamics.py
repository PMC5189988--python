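"""Correlated-motion analysis.

The dynamic cross-correlation matrix (DCCM) is the normalized covariance of
atomic positional fluctuations per residue pair.  The running cross
correlation (RCC) slides a fixed-length window one frame at a time and
recomputes the pair's correlation with window-local means, so a pair whose
coupling flips sign mid-trajectory crosses zero near the flip.  The RCC
deviation map collects the standard deviation of every pair's RCC series
and highlights pairs whose coupling changes over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import AtomSelection, Trajectory

__all__ = [
    "CorrelationMatrix",
    "dccm",
    "RCCSeries",
    "running_cross_correlation",
    "RCCDeviationMap",
    "rcc_deviation_map",
    "distance_fluctuation_map",
]

_MAX_NODES = 1000  # O(R^2 F) cost guard for the deviation map


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # (R, R), symmetric, diagonal 1
    selection: AtomSelection


def _displacements(traj: Trajectory, sel: AtomSelection) -> np.ndarray:
    sel.validate(traj.topology)
    x = traj.coords[:, sel.indices]
    return x - x.mean(axis=0)


def dccm(traj: Trajectory, sel: AtomSelection) -> CorrelationMatrix:
    """C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) over all frames.

    The trajectory should already be fitted to a reference (see
    :func:`mdstates.geometry.fit_trajectory`).  Atoms with zero positional
    variance yield NaN rows, with a warning.
    """
    D = _displacements(traj, sel)
    F = D.shape[0]
    num = np.einsum("fid,fjd->ij", D, D) / F
    var = np.diagonal(num).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} immobile atoms: correlation undefined rows")
        var[zero] = np.nan
    C = num / np.sqrt(np.outer(var, var))
    np.fill_diagonal(C, np.where(zero, np.nan, 1.0))
    return CorrelationMatrix(C, sel)


@dataclass
class RCCSeries:
    pair: tuple[int, int]
    window: int
    midpoints: np.ndarray  # k + (W-1)//2
    values: np.ndarray


def _sliding_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window mean along axis 0 via cumulative sums."""
    c = np.cumsum(x, axis=0, dtype=float)
    c = np.concatenate([np.zeros_like(c[:1]), c], axis=0)
    return (c[window:] - c[:-window]) / window


def running_cross_correlation(
    traj: Trajectory,
    sel: AtomSelection,
    pair: tuple[int, int],
    window: int,
) -> RCCSeries:
    """RCC of one selection pair: the pair's correlation coefficient within
    each length-``window`` subset of frames, advanced one frame at a time,
    plotted against the window midpoint.  Means are window-local.

    ``pair`` indexes positions within the selection.
    """
    F = traj.n_frames
    if window > F:
        raise ValueError("window exceeds trajectory length")
    if window < 10:
        raise ValueError("window must span at least 10 frames")
    i, j = pair
    if window == F:
        # limit case: one window spanning the whole trajectory reproduces
        # the full correlation matrix entry exactly
        full = dccm(traj, sel).values[i, j]
        return RCCSeries((i, j), window, np.array([(window - 1) // 2]), np.array([full]))
    x = traj.coords[:, sel.indices]
    xi, xj = x[:, i], x[:, j]
    mi = _sliding_mean(xi, window)
    mj = _sliding_mean(xj, window)
    mii = _sliding_mean((xi * xi).sum(1), window)
    mjj = _sliding_mean((xj * xj).sum(1), window)
    mij = _sliding_mean((xi * xj).sum(1), window)
    cov = mij - (mi * mj).sum(1)
    vi = mii - (mi * mi).sum(1)
    vj = mjj - (mj * mj).sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = cov / np.sqrt(vi * vj)
    mid = np.arange(F - window + 1) + (window - 1) // 2
    return RCCSeries((i, j), window, mid, vals)


@dataclass
class RCCDeviationMap:
    sigma: np.ndarray  # (R, R), symmetric, diagonal 0
    window: int


def rcc_deviation_map(
    traj: Trajectory,
    sel: AtomSelection,
    window: int | None = None,
) -> RCCDeviationMap:
    """Standard deviation of the RCC series for every selection pair.

    Default window is F // 10 (long enough to smooth out short-term
    fluctuations while resolving a mid-trajectory change in coupling).
    Vectorized with sliding sums; guarded to <= 1000 selection atoms.
    """
    F = traj.n_frames
    if window is None:
        window = max(10, F // 10)
    if window > F:
        raise ValueError("window exceeds trajectory length")
    if window < 10:
        raise ValueError("window must span at least 10 frames")
    R = len(sel)
    if R > _MAX_NODES:
        raise ValueError(
            f"selection has {R} atoms (> {_MAX_NODES}); restrict the selection "
            "(e.g. one Calpha per residue) or analyse pairs individually"
        )
    x = traj.coords[:, sel.indices]  # (F, R, 3)
    M = _sliding_mean(x, window)  # (Wn, R, 3)
    Msq = _sliding_mean((x * x).sum(2), window)  # (Wn, R)
    var = Msq - (M * M).sum(2)
    sigma = np.zeros((R, R))
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(R):
            prod = (x[:, i, None, :] * x).sum(2)  # (F, R)
            mprod = _sliding_mean(prod, window)  # (Wn, R)
            cov = mprod - (M[:, i, None, :] * M).sum(2)
            corr = cov / np.sqrt(var[:, i, None] * var)
            sigma[i] = np.nanstd(corr, axis=0)
    np.fill_diagonal(sigma, 0.0)
    sigma = 0.5 * (sigma + sigma.T)  # symmetrize away floating-point noise
    return RCCDeviationMap(sigma, window)


def distance_fluctuation_map(traj: Trajectory, sel: AtomSelection) -> np.ndarray:
    """Per-pair standard deviation of the inter-atom distance over frames.

    Needs no fitting: pairwise distances are rigid-motion invariant.
    """
    sel.validate(traj.topology)
    x = traj.coords[:, sel.indices]
    F, R, _ = x.shape

    def frame_distances(f: int) -> np.ndarray:
        diff = x[f][:, None, :] - x[f][None, :, :]
        return np.sqrt((diff * diff).sum(2))

    # two passes: the naive E[d^2]-E[d]^2 form loses ~7 digits to
    # cancellation, which matters for rigid-body (zero-fluctuation) input
    mean = np.zeros((R, R))
    for f in range(F):
        mean += frame_distances(f)
    mean /= F
    var = np.zeros((R, R))
    for f in range(F):
        dev = frame_distances(f) - mean
        var += dev * dev
    sigma = np.sqrt(var / F)
    np.fill_diagonal(sigma, 0.0)
    return sigma
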