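"""Tail-tissue morphometrics and group comparison.

Tissue lengths are piecewise-linear (segmented-line) measurements along
2D polylines with landmark points at somite boundaries; derived
quantities are the per-somite segment lengths, the developmental-stage
normalisation to µm/somite, the spinal-cord over paraxial-mesoderm
length ratio, and apoptosis fractions.  Groups of embryos are compared
with the two-sided Mann-Whitney-Wilcoxon test — exact by full
enumeration of group assignments for combined n <= 20, a normal
approximation with tie correction above that — and assigned the usual
significance tiers (* P<=0.05, ** P<=0.01, *** P<=0.001, **** P<=0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "MeasuredPolyline",
    "TissueLengths",
    "GroupComparison",
    "polyline_length",
    "relative_length",
    "tissue_ratio",
    "apoptosis_fraction",
    "compare_groups",
]

TIER_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)
TIER_LABELS = ("*", "**", "***", "****")


@dataclass
class MeasuredPolyline:
    """Ordered 2D landmark points along a tissue (µm).

    ``landmark_indices`` mark somite boundaries (and the PSM start/end)
    as strictly increasing indices into ``points_um``.
    """

    points_um: np.ndarray
    landmark_indices: tuple[int, ...] = ()
    tissue: str = "other"

    def __post_init__(self) -> None:
        self.points_um = np.atleast_2d(np.asarray(self.points_um, dtype=float))
        if self.points_um.ndim != 2 or self.points_um.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {self.points_um.shape}")
        if len(self.points_um) < 2:
            raise ValueError("a polyline needs at least 2 points")
        self.landmark_indices = tuple(int(i) for i in self.landmark_indices)
        if self.landmark_indices:
            diffs = np.diff(self.landmark_indices)
            if np.any(diffs <= 0):
                raise ValueError("landmark indices must be strictly increasing")
            if self.landmark_indices[0] < 0 or self.landmark_indices[-1] >= len(self.points_um):
                raise ValueError("landmark indices out of range")


@dataclass
class TissueLengths:
    """Lengths (µm) measured along one tissue polyline."""

    total_um: float
    per_segment_um: tuple[float, ...] = ()
    tissue: str = "other"
    total_somites: int | None = None

    @property
    def relative_um_per_somite(self) -> float | None:
        if self.total_somites is None:
            return None
        return relative_length(self.total_um, self.total_somites)


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    tier: str
    method: str
    n_a: int
    n_b: int


def polyline_length(polyline: MeasuredPolyline) -> TissueLengths:
    """Total and per-landmark-segment length of a segmented line.

    The total is the sum of Euclidean distances between consecutive
    points; each landmark segment is the portion between consecutive
    landmark indices.
    """
    pts = polyline.points_um
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cumulative = np.concatenate([[0.0], np.cumsum(seg)])
    per_segment = tuple(
        float(cumulative[j] - cumulative[i])
        for i, j in zip(polyline.landmark_indices[:-1], polyline.landmark_indices[1:])
    )
    return TissueLengths(float(cumulative[-1]), per_segment, polyline.tissue)


def relative_length(total_um: float, total_somites: int) -> float:
    """Length normalised by somite number; units µm/somite."""
    if total_somites < 1:
        raise ValueError(f"total_somites must be >= 1, got {total_somites}")
    return float(total_um) / int(total_somites)


def tissue_ratio(sc: TissueLengths, pm: TissueLengths) -> float:
    """Spinal-cord length relative to paraxial-mesoderm length.

    Both lengths must be measured from the same anterior landmark (by
    convention the 22nd somite).
    """
    if pm.total_um <= 0:
        raise ValueError("paraxial mesoderm length must be positive")
    if sc.total_um <= 0:
        raise ValueError("spinal cord length must be positive")
    return sc.total_um / pm.total_um


def apoptosis_fraction(positive_count: int, nuclei_count: int) -> float:
    """Percentage of nuclei positive for an apoptosis marker."""
    if nuclei_count < 1:
        raise ValueError("nuclei_count must be >= 1")
    if not 0 <= positive_count <= nuclei_count:
        raise ValueError(
            f"positive_count {positive_count} outside [0, {nuclei_count}]"
        )
    return 100.0 * positive_count / nuclei_count


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon
# ---------------------------------------------------------------------------

def _u_statistic(ranks: np.ndarray, idx_a, n_a: int) -> float:
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def _tier(p: float, thresholds=TIER_THRESHOLDS) -> str:
    t_star, t_2, t_3, t_4 = thresholds
    if p <= t_4:
        return "****"
    if p <= t_3:
        return "***"
    if p <= t_2:
        return "**"
    if p <= t_star:
        return "*"
    return "ns"


def compare_groups(
    a,
    b,
    tier_thresholds=TIER_THRESHOLDS,
    exact_max_n: int = 20,
) -> GroupComparison:
    """Two-sided Mann-Whitney-Wilcoxon comparison of two groups.

    For combined sample sizes up to ``exact_max_n`` the p-value is exact
    by full enumeration of all group assignments (the two-sided p is the
    fraction of assignments whose U deviates from its null mean at least
    as much as observed, which handles ties via midranks).  Larger
    samples use the normal approximation with tie correction.  The
    reported U is that of group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one value")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n_a), n_a)

    if n_a + n_b <= exact_max_n:
        mu = n_a * n_b / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks, idx, n_a)
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
            total += 1
        p = hits / total
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u_obs = float(res.statistic)
        p = float(res.pvalue)
        method = "asymptotic"
    return GroupComparison(u_obs, float(min(p, 1.0)), _tier(p, tier_thresholds),
                           method, n_a, n_b)
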