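"""Statistical association between structural attributes and conformational
states.

Binary attributes (H-bond / salt-bridge / contact presence) are scored with
the PHI coefficient; continuous attributes (SASA, distances) with the
point-biserial correlation; backbone angles are first mapped through a sine
transform.  Welch's two-tailed t-test compares continuous group means and
the Watson-Williams high-concentration F test compares circular means.
The screen flags attributes whose |r| exceeds a threshold (0.5 by default)
and reports the state each attribute associates with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AlignmentError, AttributeSeries, StateLabels

__all__ = [
    "StateCorrelationResult",
    "phi_coefficient",
    "point_biserial",
    "circular_correlation_input",
    "two_sample_t",
    "watson_williams",
    "screen_attributes",
]


@dataclass
class StateCorrelationResult:
    attribute_id: str
    statistic_kind: str  # phi | point_biserial | pearson | t | watson_williams_F
    statistic_value: float
    p_value: float
    associated_state: str  # closed | open | none
    flagged: bool = False
    q_value: float = float("nan")  # Benjamini-Hochberg, reported, not used


def phi_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """PHI coefficient of two binary series from the 2x2 contingency table.

    Equals the Pearson correlation of the two 0/1 variables.  Returns NaN
    (undefined-statistic marker) when either series is constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    if not (np.all(np.isin(a, (0, 1))) and np.all(np.isin(b, (0, 1)))):
        raise ValueError("phi_coefficient requires binary 0/1 input")
    n11 = float(np.sum((a == 1) & (b == 1)))
    n10 = float(np.sum((a == 1) & (b == 0)))
    n01 = float(np.sum((a == 0) & (b == 1)))
    n00 = float(np.sum((a == 0) & (b == 0)))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def phi_p_value(phi: float, n: int) -> float:
    """Two-sided p for a PHI coefficient via the chi-square statistic n*phi^2."""
    if np.isnan(phi):
        return float("nan")
    return float(stats.chi2.sf(n * phi * phi, df=1))


def point_biserial(labels: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Point-biserial correlation (r, two-sided p) of a 0/1 grouping against
    a continuous variable; identical to the Pearson r of x vs labels.
    Returns (NaN, NaN) when a group is empty or x is constant."""
    labels = np.asarray(labels, dtype=float)
    x = np.asarray(x, dtype=float)
    if labels.shape != x.shape:
        raise ValueError("series lengths differ")
    if len(np.unique(labels)) < 2 or np.ptp(x) == 0:
        return float("nan"), float("nan")
    r, p = stats.pointbiserialr(labels, x)
    return float(r), float(p)


def circular_correlation_input(angles_deg: np.ndarray) -> np.ndarray:
    """Sine transform mapping angles (degrees) onto a linear scale for
    correlation analysis."""
    return np.sin(np.radians(np.asarray(angles_deg, dtype=float)))


def two_sample_t(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and two-tailed p.

    Both groups need n >= 2.  Two zero-variance groups with equal means
    return (0, 1) by convention.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x0.size < 2 or x1.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(x0) == 0 and np.ptp(x1) == 0:
        if x0[0] == x1[0]:
            return 0.0, 1.0
        return float("inf") if x1[0] < x0[0] else float("-inf"), 0.0
    t, p = stats.ttest_ind(x0, x1, equal_var=False)
    return float(t), float(p)


def _resultant_length(angles_rad: np.ndarray) -> float:
    return float(np.hypot(np.cos(angles_rad).sum(), np.sin(angles_rad).sum()))


def kappa_ml(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from the mean resultant
    length, via the standard three-regime rational approximation."""
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)


def watson_williams(
    angles0_deg: np.ndarray, angles1_deg: np.ndarray
) -> tuple[float, float]:
    """Watson-Williams high-concentration F test of equal mean directions.

    F = K (N-2) (R1 + R2 - R) / (N - R1 - R2) with K = 1 + 3/(8 kappa),
    kappa estimated from the pooled mean resultant length; p from F(1, N-2).
    Validity requires concentrated data (pooled R-bar >= 0.45, warned below).
    """
    a0 = np.radians(np.asarray(angles0_deg, dtype=float))
    a1 = np.radians(np.asarray(angles1_deg, dtype=float))
    if a0.size < 5 or a1.size < 5:
        raise ValueError("each group needs at least 5 angles")
    n0, n1 = a0.size, a1.size
    N = n0 + n1
    pooled = np.concatenate([a0, a1])
    if np.ptp(pooled) == 0:
        return float("nan"), float("nan")
    R0 = _resultant_length(a0)
    R1 = _resultant_length(a1)
    R = _resultant_length(pooled)
    rbar = R / N
    if rbar < 0.45:
        warnings.warn(
            f"pooled mean resultant length {rbar:.2f} < 0.45: "
            "Watson-Williams high-concentration assumption is violated"
        )
    kappa = kappa_ml(rbar)
    K = 1.0 + 3.0 / (8.0 * kappa)
    denom = N - R0 - R1
    if denom <= 0:
        return float("nan"), float("nan")
    F = K * (N - 2) * (R0 + R1 - R) / denom
    F = max(F, 0.0)
    p = float(stats.f.sf(F, 1, N - 2))
    return float(F), p


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def screen_attributes(
    attrs: list[AttributeSeries],
    labels: StateLabels,
    r_threshold: float = 0.5,
) -> list[StateCorrelationResult]:
    """State-correlation screen over a list of attribute series.

    Binary kinds are scored by PHI against the per-frame state label;
    angles by point-biserial correlation of their sine transform; other
    continuous kinds by point-biserial correlation directly.  A positive
    statistic means the attribute is elevated/present in the open state.
    Results are sorted by |statistic| (undefined statistics last) and
    carry BH q-values for transparency (flagging uses |r| only).
    """
    lab = labels.labels
    out: list[StateCorrelationResult] = []
    pvals: list[float] = []
    for attr in attrs:
        if attr.frame_index.size and attr.frame_index.max() >= lab.size:
            raise AlignmentError(
                f"{attr.id}: frame index {int(attr.frame_index.max())} outside "
                f"the {lab.size}-frame label array (stride mismatch?)"
            )
        y = lab[attr.frame_index].astype(float)
        if attr.kind in AttributeSeries.BINARY_KINDS:
            r = phi_coefficient(attr.values, y)
            p = phi_p_value(r, attr.values.size)
            kind = "phi"
        elif attr.kind in ("phi", "psi"):
            r, p = point_biserial(y, circular_correlation_input(attr.values))
            kind = "point_biserial"
        else:
            r, p = point_biserial(y, attr.values)
            kind = "point_biserial"
        if np.isnan(r):
            flagged = False
        else:
            flagged = abs(r) > r_threshold
        state = ("open" if r > 0 else "closed") if flagged else "none"
        out.append(StateCorrelationResult(attr.id, kind, r, p, state, flagged))
        pvals.append(p)
    q = _bh_qvalues(np.asarray(pvals, dtype=float))
    for res, qv in zip(out, q):
        res.q_value = float(qv)
    out.sort(key=lambda r: (np.isnan(r.statistic_value), -abs(r.statistic_value)))
    return out
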