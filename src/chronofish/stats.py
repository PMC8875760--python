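"""Group-level statistics: circular means, Watson–Williams, Wilcoxon, BH,
two-cluster heat-map analysis, and dark-flash response extraction.

Phases live on a circle (24 circadian hours), so group phases are compared
with circular statistics: the descriptive summary is the (weighted) mean
direction with its resultant length R̄, and group differences in mean
direction are tested with the Watson–Williams F test.  Linear quantities
(period, amplitude, G-factor) are compared with the Wilcoxon rank-sum test,
and families of pairwise comparisons are adjusted by the Benjamini–Hochberg
step-up procedure at FDR 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .containers import ActivityTrace

__all__ = [
    "CircularSample",
    "TestResult",
    "ClusterResult",
    "circular_mean",
    "watson_williams",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "cluster_subjects",
    "flash_response",
    "phases_to_angles",
]


@dataclass
class CircularSample:
    """Angles in radians (optionally weighted) for one group."""

    angles: np.ndarray
    weights: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.angles.shape:
                raise ValueError("weights must match angles")
            if np.any(self.weights < 0):
                raise ValueError("weights must be >= 0")

    @property
    def n(self) -> int:
        return int(self.angles.size)


def phases_to_angles(phases_h, circle_h: float = 24.0) -> np.ndarray:
    """Map phases in hours on a ``circle_h`` circle to radians."""
    return 2.0 * np.pi * np.asarray(phases_h, dtype=float) / circle_h


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def circular_mean(sample: CircularSample | np.ndarray, weights=None) -> tuple[float, float]:
    """Weighted mean direction and resultant length R̄ of circular data.

    Returns ``(mean_direction_rad, R̄)`` with R̄ = |Σw·e^{iθ}|/Σw ∈ [0, 1];
    a zero resultant (perfectly balanced angles) leaves the mean undefined
    and raises.
    """
    if isinstance(sample, CircularSample):
        angles, w = sample.angles, sample.weights
    else:
        angles, w = np.asarray(sample, dtype=float), weights
    if w is None:
        w = np.ones_like(angles)
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    s = float(np.sum(w * np.sin(angles)))
    c = float(np.sum(w * np.cos(angles)))
    rbar = float(np.hypot(s, c) / total)
    if rbar < 1e-12:
        raise ValueError("mean direction undefined: zero resultant length")
    return float(np.arctan2(s, c)), rbar


def _kappa_from_rbar(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from R̄ (Fisher's approximation)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(groups: list[CircularSample]) -> TestResult:
    """Watson–Williams F test for homogeneity of circular mean directions.

    The classical test with the concentration correction factor
    K = 1 + 3/(8κ̂), κ̂ estimated from the pooled within-group mean resultant
    length.  A warning flag is attached when pooled R̄ < 0.7, where the
    test's concentration assumption is strained.  Weights are ignored: the
    test is defined for unweighted samples.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError("each group needs n >= 2")
    ns = tuple(g.n for g in groups)
    N = int(sum(ns))
    k = len(groups)
    R_i = []
    S = C = 0.0
    for g in groups:
        s = float(np.sum(np.sin(g.angles)))
        c = float(np.sum(np.cos(g.angles)))
        R_i.append(np.hypot(s, c))
        S += s
        C += c
    sumR = float(np.sum(R_i))
    R = float(np.hypot(S, C))
    if N - sumR < 1e-12:
        raise ValueError("degenerate dispersion: zero within-group spread")
    rbar_w = sumR / N
    kappa = _kappa_from_rbar(min(rbar_w, 1 - 1e-12))
    K = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    F = K * ((N - k) * (sumR - R)) / ((k - 1) * (N - sumR))
    F = max(F, 0.0)
    p = float(sps.f.sf(F, k - 1, N - k))
    warns = ()
    if rbar_w < 0.7:
        warns = (
            f"pooled mean resultant length {rbar_w:.3f} < 0.7: "
            "Watson-Williams concentration assumption strained",
        )
    return TestResult(statistic=float(F), p_value=p, method="watson_williams", n=ns, warnings=warns)


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon (Mann–Whitney) rank-sum test.

    Exact p by full enumeration of the U distribution when the combined
    sample has ≤ 20 observations and no ties; otherwise mid-ranks with the
    tie-corrected normal approximation (no continuity correction).  The
    method used is recorded in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    if a.size + b.size <= 20 and no_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "wilcoxon_rank_sum_exact"
    else:
        if np.unique(combined).size == 1:
            # All observations identical: no evidence of any shift.
            return TestResult(
                statistic=float(a.size * b.size / 2.0),
                p_value=1.0,
                method="wilcoxon_rank_sum_normal_approx",
                n=(int(a.size), int(b.size)),
                warnings=("all observations identical",),
            )
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        method = "wilcoxon_rank_sum_normal_approx"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n=(int(a.size), int(b.size)),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: np.ndarray
    order: np.ndarray
    statistic: float
    p_value: float
    n_perm: int
    seed: int | None


def _agreement(cluster_labels: np.ndarray, group_labels: np.ndarray) -> float:
    """Best-matching fraction of subjects whose cluster matches their group."""
    clusters = np.unique(cluster_labels)
    groups = np.unique(group_labels)
    if clusters.size != 2 or groups.size != 2:
        raise ValueError("agreement statistic defined for 2 clusters x 2 groups")
    match = (cluster_labels == clusters[0]) == (group_labels == groups[0])
    acc = match.mean()
    return float(max(acc, 1.0 - acc))


def cluster_subjects(
    activity_matrix: np.ndarray,
    group_labels,
    k: int = 2,
    n_perm: int = 10_000,
    seed: int | None = None,
    metric: str = "correlation",
    method: str = "average",
) -> ClusterResult:
    """Hierarchical two-cluster analysis of per-subject activity profiles.

    Rows are (mean-normalized) subject traces.  Subjects are clustered by
    correlation distance with average linkage; the tree is cut at ``k``
    clusters and the leaf order is returned for heat-map display.  The
    association between cluster membership and group labels is assessed by
    permuting group labels: the statistic is the best-matching
    cluster–genotype agreement, and p has resolution 1/(n_perm + 1).
    """
    X = np.asarray(activity_matrix, dtype=float)
    group_labels = np.asarray(group_labels)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need a 2-d matrix with at least 4 subjects")
    if group_labels.size != X.shape[0]:
        raise ValueError("one group label per subject required")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant activity rows (undefined correlation): subjects {bad}")
    dist = pdist(X, metric=metric)
    if np.any(~np.isfinite(dist)):
        raise ValueError("degenerate distances between subjects")
    Z = linkage(dist, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    order = leaves_list(Z)
    obs = _agreement(labels, group_labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(group_labels)
        if _agreement(labels, perm) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return ClusterResult(
        linkage=Z, labels=labels, order=order, statistic=obs, p_value=p,
        n_perm=n_perm, seed=seed,
    )


def flash_response(
    trace: ActivityTrace,
    flash_events: list[tuple[float, float]],
    window_min: float = 10.0,
) -> pd.DataFrame:
    """Mean activity before, during, and after each dark flash.

    ``flash_events`` are ``(start_h, duration_s)`` pairs.  For each event the
    before-window is the ``window_min`` minutes preceding the flash, the
    during-window the flash itself, and the after-window the ``window_min``
    minutes following it.  Bin values are averaged with overlap weighting
    (bins are coarser than a 10-s flash).  Group comparison of the returned
    means is delegated to :func:`wilcoxon_rank_sum`.
    """
    bin_h = trace.bin_min / 60.0
    span_h = trace.values.size * bin_h
    win_h = window_min / 60.0
    events = sorted((float(s), float(d)) for s, d in flash_events)
    windows = []
    for start_h, duration_s in events:
        dur_h = duration_s / 3600.0
        lo, hi = start_h - win_h, start_h + dur_h + win_h
        if lo < -1e-9 or hi > span_h + 1e-9:
            raise ValueError(f"flash at {start_h} h: analysis window outside recording")
        windows.append((lo, hi))
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError("overlapping flash analysis windows")

    edges = np.arange(trace.values.size + 1) * bin_h

    def window_mean(lo: float, hi: float) -> float:
        w = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)
        if w.sum() <= 0:
            raise ValueError("empty analysis window")
        return float(np.average(trace.values, weights=w))

    rows = []
    for i, (start_h, duration_s) in enumerate(events):
        dur_h = duration_s / 3600.0
        rows.append(
            {
                "event": i,
                "start_h": start_h,
                "before": window_mean(start_h - win_h, start_h),
                "during": window_mean(start_h, start_h + dur_h),
                "after": window_mean(start_h + dur_h, start_h + dur_h + win_h),
            }
        )
    return pd.DataFrame(rows)
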