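"""SAXS agreement metrics.

Theoretical scattering by the Debye formula with q-independent per-element
form factors (electron counts), Guinier Rg extraction from curves,
direct-space P(r) histograms with Dmax, reduced chi-square fitting of a
scaled theoretical curve to an experimental one, and per-state chi-square
statistics over a labelled trajectory.

Hydration-shell and excluded-volume corrections are deliberately not
modelled; absolute chi-square values against real solution data will
therefore differ from hydration-aware predictors.  The metrics are
designed for coordinate-space consistency checks (Rg, Dmax, relative
state-to-state comparisons).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from . import elements
from .core import StateLabels, Structure, Trajectory

__all__ = [
    "ScatteringCurve",
    "PofR",
    "read_saxs",
    "write_saxs",
    "form_factors",
    "debye_curve",
    "guinier_rg",
    "InvalidGuinierError",
    "pair_distribution",
    "intensity_from_pofr",
    "chi_square_fit",
    "per_state_chi2",
    "PerStateChi2",
]

_DEBYE_GUARD = 20_000


class InvalidGuinierError(ValueError):
    pass


@dataclass
class ScatteringCurve:
    q: np.ndarray  # 1/A, ascending
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity lengths differ")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly ascending")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length differs from q")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")


@dataclass
class PofR:
    """Pair-distance distribution: histogram weights per r bin, support
    ending at dmax."""

    r: np.ndarray  # bin centres, A
    p: np.ndarray  # >= 0
    dmax: float
    self_term: float = 0.0  # sum of f_i^2, needed to rebuild I(q)


def read_saxs(path: str | os.PathLike) -> ScatteringCurve:
    """Read a 3-column (q, I, sigma) or 2-column text curve; '#' comments."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(data[:, 0], data[:, 1], sigma)


def write_saxs(path: str | os.PathLike, curve: ScatteringCurve) -> None:
    cols = [curve.q, curve.intensity]
    header = "q I(q)"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        header += " sigma"
    np.savetxt(path, np.column_stack(cols), header=header)


def form_factors(s: Structure) -> np.ndarray:
    """Constant (q-independent) form factors: electron counts per atom."""
    return np.array([elements.electrons_of(e) for e in s.elements], dtype=float)


def _sinc(x: np.ndarray) -> np.ndarray:
    # sin(x)/x with the x -> 0 limit; np.sinc uses the normalized convention
    return np.sinc(x / np.pi)


def debye_curve(
    coords: np.ndarray,
    f: np.ndarray,
    q_grid: np.ndarray,
    chunk: int = 2_000_000,
) -> ScatteringCurve:
    """Debye-formula scattering curve:

        I(q) = sum_i sum_j f_i f_j sin(q r_ij) / (q r_ij)

    computed over atom pairs in memory-bounded chunks.  Guarded to
    ``coords`` of <= 20000 points (O(N^2) cost).
    """
    coords = np.asarray(coords, dtype=float)
    f = np.asarray(f, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    n = coords.shape[0]
    if n > _DEBYE_GUARD:
        raise ValueError(
            f"{n} points exceed the O(N^2) guard ({_DEBYE_GUARD}); "
            "coarse-grain first (e.g. one Calpha per residue)"
        )
    if f.shape != (n,):
        raise ValueError("one form factor per atom required")
    I = np.full(q.shape, float((f ** 2).sum()))
    if n < 2:
        return ScatteringCurve(q, I)
    iu, ju = np.triu_indices(n, k=1)
    r = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    w = f[iu] * f[ju]
    for lo in range(0, r.size, chunk):
        rs = r[lo : lo + chunk]
        ws = w[lo : lo + chunk]
        I += 2.0 * (ws[None, :] * _sinc(np.outer(q, rs))).sum(axis=1)
    return ScatteringCurve(q, I)


def coarse_grain_ca(s: Structure, coords: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One Calpha bead per residue carrying the residue's total electrons."""
    coords = s.coords if coords is None else np.asarray(coords, dtype=float)
    f_atom = form_factors(s)
    beads, weights = [], []
    for (_, _, _), idx in s.residues():
        rep = next((i for i in idx if s.atoms[i].name.strip() == "CA"), idx[0])
        beads.append(coords[rep])
        weights.append(f_atom[idx].sum())
    return np.asarray(beads), np.asarray(weights)


def guinier_rg(
    curve: ScatteringCurve, qmax_rg: float = 1.3
) -> tuple[float, float, tuple[int, int]]:
    """Guinier fit ln I = ln I0 - q^2 Rg^2 / 3 on the self-consistent range
    q * Rg <= ``qmax_rg``.

    The range is determined iteratively from the fitted Rg.  Returns
    (Rg, I0, (start, stop) indices of the final fit range).  A
    non-negative slope raises :class:`InvalidGuinierError`.
    """
    q = curve.q
    I = curve.intensity
    if np.any(I <= 0):
        pos = I > 0
        q, I = q[pos], I[pos]
    if q.size < 5:
        raise InvalidGuinierError("fewer than 5 usable points")
    stop = max(5, q.size // 10)
    rg = None
    for _ in range(50):
        x = q[:stop] ** 2
        y = np.log(I[:stop])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            raise InvalidGuinierError("non-negative Guinier slope at low q")
        rg_new = float(np.sqrt(-3.0 * slope))
        new_stop = int(np.searchsorted(q, qmax_rg / rg_new, side="right"))
        new_stop = max(5, min(new_stop, q.size))
        if rg is not None and new_stop == stop:
            rg = rg_new
            break
        rg, stop = rg_new, new_stop
    i0 = float(np.exp(intercept))
    return float(rg), i0, (0, stop)


def pair_distribution(
    coords: np.ndarray,
    f: np.ndarray | None = None,
    bin_width: float = 1.0,
) -> PofR:
    """Weighted histogram of pairwise distances (weights 2 f_i f_j per
    unordered pair); dmax is the exact maximum pairwise distance."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 atoms")
    f = np.ones(n) if f is None else np.asarray(f, dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    w = 2.0 * f[iu] * f[ju]
    dmax = float(d.max())
    nbins = max(1, int(np.ceil(dmax / bin_width)))
    hist, edges = np.histogram(d, bins=nbins, range=(0.0, nbins * bin_width), weights=w)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return PofR(centres, hist, dmax, self_term=float((f ** 2).sum()))


def intensity_from_pofr(pofr: PofR, q_grid: np.ndarray) -> ScatteringCurve:
    """Rebuild I(q) from a P(r) histogram: the Debye sum over binned
    distances plus the self term."""
    q = np.asarray(q_grid, dtype=float)
    I = pofr.self_term + (pofr.p[None, :] * _sinc(np.outer(q, pofr.r))).sum(axis=1)
    return ScatteringCurve(q, I)


def chi_square_fit(
    exp: ScatteringCurve, calc: ScatteringCurve
) -> tuple[float, float]:
    """Reduced chi-square of a scaled theoretical curve against experiment:

        chi2 = (1/(N-1)) sum [(I_exp - c I_calc) / sigma]^2

    with the closed-form least-squares scale c.  The theoretical curve is
    interpolated onto the experimental q grid; non-overlapping grids raise.
    """
    qmin, qmax = calc.q[0], calc.q[-1]
    mask = (exp.q >= qmin) & (exp.q <= qmax)
    if not mask.any():
        raise ValueError("experimental and theoretical q ranges do not overlap")
    qe = exp.q[mask]
    Ie = exp.intensity[mask]
    sig = exp.sigma[mask] if exp.sigma is not None else np.ones_like(Ie)
    Ic = np.interp(qe, calc.q, calc.intensity)
    c = float((Ie * Ic / sig ** 2).sum() / (Ic ** 2 / sig ** 2).sum())
    resid = (Ie - c * Ic) / sig
    chi2 = float((resid ** 2).sum() / max(qe.size - 1, 1))
    return chi2, c


@dataclass
class PerStateChi2:
    mean: dict[int, float]
    std: dict[int, float]
    per_frame: np.ndarray  # chi2 for each sampled frame
    frames: np.ndarray
    best_frame: int
    best_state: int
    best_chi2: float


def per_state_chi2(
    traj: Trajectory,
    labels: StateLabels,
    exp: ScatteringCurve,
    stride: int = 10,
    coarse_grain: bool = True,
) -> PerStateChi2:
    """Per-frame Debye curve + chi-square fit, summarized by state.

    Frames are strided for cost; by default each frame is coarse-grained
    to one Calpha bead per residue with the residue's electrons.  Uniform
    labels give a single-state summary.
    """
    if len(labels) != traj.n_frames:
        raise ValueError("labels are not aligned to trajectory frames")
    top = traj.topology
    frames = np.arange(0, traj.n_frames, stride)
    if coarse_grain:
        _, weights = coarse_grain_ca(top)
        reps = []
        for (chain, resid, _), idx in top.residues():
            reps.append(next((i for i in idx if top.atoms[i].name.strip() == "CA"), idx[0]))
        reps = np.asarray(reps)
    else:
        weights = form_factors(top)
        reps = np.arange(top.n_atoms)
    chi = np.empty(frames.size)
    for k, fi in enumerate(frames):
        calc = debye_curve(traj.coords[fi][reps], weights, exp.q)
        chi[k], _ = chi_square_fit(exp, calc)
    lab = labels.labels[frames]
    mean = {int(s): float(chi[lab == s].mean()) for s in np.unique(lab)}
    std = {int(s): float(chi[lab == s].std()) for s in np.unique(lab)}
    best = int(np.argmin(chi))
    return PerStateChi2(
        mean, std, chi, frames, int(frames[best]), int(lab[best]), float(chi[best])
    )
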