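"""Sample-proportion scores: how many samples actually sit in the bad regions.

Two features can share the same overlapping area yet differ sharply in how
many samples fall inside it; the one whose overlap region is sparsely
populated still classifies most samples correctly.  For feature ``i`` and
class ``j``, ``H_ij`` counts class-``j`` samples inside the feature's overlap
region and ``G_ij`` counts those inside its inclusion region.  With ``K_j``
the class size, the per-feature totals are

    H_i = sum_j H_ij / K_j,      G_i = sum_j G_ij / K_j,

each bounded by the number of classes, and the normalized scores

    NH_i = 1 - H_i / max_s(H_s),   GH_i = 1 - G_i / max_s(G_s)

lie in [0, 1] with larger meaning more discriminative.  When the max is zero
(no sample anywhere in a region) the score is 1 for all features.

The counting regions are defined per class because the scalar areas do not
name a region for more than two classes: the overlap region of class ``j`` is
the union of its range's nonempty pairwise intersections with every other
class's range; the inclusion region of class ``j`` is its own range whenever
some other class's range includes it (psi fires for the oriented pair).
Intervals are closed: a value equal to an endpoint counts as inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .area_scoring import class_order
from .stats_core import ClassFeatureStats, EffectiveRangeTable, LabeledMatrix

__all__ = [
    "ProportionScores",
    "overlap_region",
    "inclusion_region",
    "proportion_scores",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class ProportionScores:
    """Per-(feature, class) region counts and the derived NH/GH scores."""

    h_counts: np.ndarray
    g_counts: np.ndarray
    h_total: np.ndarray
    g_total: np.ndarray
    nh: np.ndarray
    gh: np.ndarray


def _merge(intervals: list[Interval]) -> list[Interval]:
    """Union of closed intervals as a sorted list of disjoint intervals."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        mlo, mhi = merged[-1]
        if lo <= mhi:  # closed intervals: touching endpoints merge
            merged[-1] = (mlo, max(mhi, hi))
        else:
            merged.append((lo, hi))
    return merged


def overlap_region(
    feature: int,
    class_j: int,
    ranges: EffectiveRangeTable,
) -> list[Interval]:
    """Union of nonempty intersections of class ``j``'s range with every other.

    Returned as disjoint closed intervals (possibly zero-width).  Symmetric in
    the pair, so no orientation is involved.
    """
    lo = ranges.lower[feature]
    hi = ranges.upper[feature]
    pieces: list[Interval] = []
    for k in range(ranges.n_classes):
        if k == class_j:
            continue
        ilo = max(lo[class_j], lo[k])
        ihi = min(hi[class_j], hi[k])
        if ilo <= ihi:
            pieces.append((ilo, ihi))
    return _merge(pieces)


def inclusion_region(
    feature: int,
    class_j: int,
    ranges: EffectiveRangeTable,
    mode: str = "sorted",
    convention: str = "included",
) -> list[Interval]:
    """Region whose class-``j`` samples count toward ``G_ij``.

    Class pairs are oriented as in the area sums (``mode``); for each oriented
    pair (a, b) with ``r_a+ >= r_b+`` the included range is ``R_b``.  Under the
    default ``included`` convention only the included class's own samples are
    counted, so class ``j``'s region is ``R_j`` whenever some pair includes it;
    under ``both`` the including class's samples inside ``R_b`` count too.
    """
    if convention not in ("included", "both"):
        raise ValueError(f"unknown convention {convention!r}")
    order = class_order(ranges, mode)[feature]
    lo = ranges.lower[feature]
    hi = ranges.upper[feature]
    l = len(order)
    pieces: list[Interval] = []
    for a_pos in range(l - 1):
        for b_pos in range(a_pos + 1, l):
            a, b = int(order[a_pos]), int(order[b_pos])
            if hi[a] >= hi[b]:  # psi fires; b is the included class
                if class_j == b or (convention == "both" and class_j == a):
                    pieces.append((lo[b], hi[b]))
    return _merge(pieces)


def _count_in(values: np.ndarray, region: list[Interval]) -> int:
    """Number of values inside a union of closed intervals."""
    if not region:
        return 0
    inside = np.zeros(values.shape, dtype=bool)
    for lo, hi in region:
        inside |= (values >= lo) & (values <= hi)
    return int(inside.sum())


def proportion_scores(
    data: LabeledMatrix,
    stats: ClassFeatureStats,
    ranges: EffectiveRangeTable,
    mode: str = "sorted",
    convention: str = "included",
) -> ProportionScores:
    """Count samples in overlap/inclusion regions and normalize across features."""
    d, l = ranges.lower.shape
    if stats.mu.shape != (d, l) or data.n_features != d or stats.n_classes != l:
        raise ValueError("data/stats/ranges shapes are inconsistent")
    class_masks = [data.labels == cls for cls in stats.classes]
    counts = np.array([int(m.sum()) for m in class_masks])
    if not np.array_equal(counts, stats.class_size):
        raise ValueError(
            f"data/stats class mismatch: sizes {counts.tolist()} in data vs "
            f"{stats.class_size.tolist()} in stats for classes {list(stats.classes)}"
        )
    h_counts = np.zeros((d, l), dtype=int)
    g_counts = np.zeros((d, l), dtype=int)
    for i in range(d):
        col = data.values[:, i]
        for j in range(l):
            h_reg = overlap_region(i, j, ranges)
            vals = col[class_masks[j]]
            if h_reg:
                h_counts[i, j] = _count_in(vals, h_reg)
            g_reg = inclusion_region(i, j, ranges, mode=mode, convention=convention)
            if g_reg:
                g_counts[i, j] = _count_in(vals, g_reg)
    k = stats.class_size.astype(float)
    h_total = (h_counts / k).sum(axis=1)
    g_total = (g_counts / k).sum(axis=1)
    nh = 1.0 - h_total / h_total.max() if h_total.max() > 0 else np.ones(d)
    gh = 1.0 - g_total / g_total.max() if g_total.max() > 0 else np.ones(d)
    return ProportionScores(
        h_counts=h_counts,
        g_counts=g_counts,
        h_total=h_total,
        g_total=g_total,
        nh=nh,
        gh=gh,
    )
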