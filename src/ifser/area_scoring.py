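"""Interval-geometry feature scores: overlapping and including areas.

For one feature, each class contributes an effective range.  Two classes whose
ranges overlap are confusable on that feature; the *overlapping area* (OA)
sums, over ordered class pairs (j, k),

    phi(j, k) = r_j+ - r_k-   if r_j+ > r_k-,  else 0.

A range fully nested inside another is a distinct failure mode (every sample
of the inner class sits inside the outer class's range); the *including area*
(IA) sums the widths of included ranges,

    psi(j, k) = r_k+ - r_k-   if r_j+ >= r_k+,  else 0.

Both formulas are asymmetric in (j, k).  In the default ``sorted`` mode the
classes of each feature are ordered ascending by lower bound (ties by upper
bound, then class index) before the j < k double sums, so that phi measures
left-to-right overlap and psi's upper-bound test coincides with true
inclusion.  ``literal`` mode applies the formulas in the original class-label
order.

SA = OA + IA is normalized by the hull width into the area coefficient
AC = SA / (max_j r_j+ - min_j r_j-), and across features into
NAC = 1 - AC / max(AC), so the least-confusable feature scores 1.
Note that in an inclusion configuration phi also fires, so SA counts the
included region more than once; this is the formulas as printed.  The
``exclusive`` flag subtracts psi from phi whenever both fire.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats_core import EffectiveRangeTable

__all__ = [
    "AreaScores",
    "pairwise_phi",
    "pairwise_psi",
    "class_order",
    "area_decomposition",
    "ergs_weights",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class AreaScores:
    """Per-feature overlap/inclusion areas and (normalized) area coefficients."""

    oa: np.ndarray
    ia: np.ndarray
    sa: np.ndarray
    ac: np.ndarray
    nac: np.ndarray


def pairwise_phi(range_j: Interval, range_k: Interval) -> float:
    """Overlap contribution of one oriented class pair.

    Returns ``r_j+ - r_k-`` when positive, else 0.  The caller is responsible
    for pair orientation (see :func:`class_order`); for sorted pairs in a
    non-inclusion configuration this equals the intersection length.
    """
    lo_j, hi_j = range_j
    lo_k, hi_k = range_k
    if lo_j > hi_j or lo_k > hi_k:
        raise ValueError("invalid interval (lower > upper)")
    return hi_j - lo_k if hi_j > lo_k else 0.0


def pairwise_psi(range_j: Interval, range_k: Interval) -> float:
    """Inclusion contribution: the width of ``range_k`` when ``r_j+ >= r_k+``.

    Only the upper bounds are compared, as printed; for pairs sorted ascending
    by lower bound the condition is equivalent to true inclusion.
    """
    lo_j, hi_j = range_j
    lo_k, hi_k = range_k
    if lo_j > hi_j or lo_k > hi_k:
        raise ValueError("invalid interval (lower > upper)")
    return hi_k - lo_k if hi_j >= hi_k else 0.0


def class_order(ranges: EffectiveRangeTable, mode: str = "sorted") -> np.ndarray:
    """Per-feature class ordering applied before the pairwise double sums.

    Returns a ``(d, l)`` integer array; row ``i`` is the class permutation for
    feature ``i``.  ``sorted``: ascending lower bound, ties by upper bound,
    then class index.  ``literal``: the identity (original label order).
    """
    d, l = ranges.lower.shape
    if mode == "literal":
        return np.broadcast_to(np.arange(l), (d, l)).copy()
    if mode != "sorted":
        raise ValueError(f"unknown mode {mode!r}")
    idx = np.broadcast_to(np.arange(l), (d, l))
    # lexsort: last key is primary
    return np.lexsort((idx, ranges.upper, ranges.lower), axis=-1)


def _pair_areas(
    ranges: EffectiveRangeTable,
    mode: str,
    include_ia: bool,
    exclusive: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OA/IA double sums over oriented class pairs."""
    order = class_order(ranges, mode)
    lo = np.take_along_axis(ranges.lower, order, axis=1)
    hi = np.take_along_axis(ranges.upper, order, axis=1)
    d, l = lo.shape
    oa = np.zeros(d)
    ia = np.zeros(d)
    for j in range(l - 1):
        for k in range(j + 1, l):
            phi = np.where(hi[:, j] > lo[:, k], hi[:, j] - lo[:, k], 0.0)
            psi = np.where(hi[:, j] >= hi[:, k], hi[:, k] - lo[:, k], 0.0)
            if not include_ia:
                psi = np.zeros(d)
            if exclusive:
                phi = np.where((phi > 0) & (psi > 0), phi - psi, phi)
            oa += phi
            ia += psi
    return oa, ia


def _normalize_area(sa: np.ndarray, hull: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AC = SA/hull (0 where the hull is degenerate); NAC = 1 - AC/max(AC)."""
    ac = np.zeros_like(sa)
    np.divide(sa, hull, out=ac, where=hull > 0)
    ac_max = ac.max() if ac.size else 0.0
    if ac_max > 0:
        nac = 1.0 - ac / ac_max
    else:
        nac = np.ones_like(ac)
    return ac, nac


def area_decomposition(
    ranges: EffectiveRangeTable,
    mode: str = "sorted",
    include_ia: bool = True,
    exclusive: bool = False,
) -> AreaScores:
    """Per-feature OA, IA, SA, AC and NAC from an effective-range table.

    Parameters
    ----------
    ranges
        The ``(d, l)`` effective-range table.
    mode
        ``sorted`` (orient class pairs by ascending lower bound, the default)
        or ``literal`` (original class order, formulas verbatim).
    include_ia
        When False the including area is forced to zero, reducing SA to OA —
        exactly the quantity the OA-only predecessor method normalizes.
    exclusive
        Subtract psi from phi when both fire, so the included region is not
        counted twice in SA.
    """
    if ranges.n_classes < 2:
        raise ValueError("need at least 2 classes")
    oa, ia = _pair_areas(ranges, mode, include_ia, exclusive)
    sa = oa + ia
    hull = ranges.upper.max(axis=1) - ranges.lower.min(axis=1)
    ac, nac = _normalize_area(sa, hull)
    return AreaScores(oa=oa, ia=ia, sa=sa, ac=ac, nac=nac)


def ergs_weights(ranges: EffectiveRangeTable, mode: str = "sorted") -> np.ndarray:
    """OA-only feature weights: the normalized area coefficient with SA = OA.

    This is the predecessor scheme (effective-range based gene selection):
    rank features by the NAC of their overlapping area alone, ignoring
    inclusion and sample proportions.
    """
    return area_decomposition(ranges, mode=mode, include_ia=False).nac
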