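"""Core interval algebra.

Overlap with reciprocal-fraction semantics, bookend-preserving merge,
nearest-anchor distances, winnum-style windowing and element/bp Jaccard.
All functions take sorted lists of :class:`GenomicInterval`; abutting
half-open intervals ([0,10), [10,20)) do not overlap and are not merged.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .models import GenomicInterval, OverlapRule, ANY_OVERLAP


class UnsortedInputError(ValueError):
    pass


def _check_sorted(intervals, what: str) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise UnsortedInputError(
                f"{what} intervals are not sorted by (chrom, start); sort them first")


def _by_chrom(intervals):
    d: dict[str, list[tuple[int, GenomicInterval]]] = defaultdict(list)
    for i, iv in enumerate(intervals):
        d[iv.chrom].append((i, iv))
    return d


def intersect(query, target, rule: OverlapRule = ANY_OVERLAP):
    """All (query_index, target_index, overlap_bp) pairs satisfying ``rule``.

    Each qualifying pair is reported exactly once, in query order.
    """
    _check_sorted(query, "query")
    _check_sorted(target, "target")
    tgt = _by_chrom(target)
    out: list[tuple[int, int, int]] = []
    for chrom, qs in _by_chrom(query).items():
        ts = tgt.get(chrom)
        if not ts:
            continue
        t_start = np.array([iv.start for _, iv in ts])
        t_end = np.array([iv.end for _, iv in ts])
        for qi, q in qs:
            hits = np.nonzero((t_start < q.end) & (t_end > q.start))[0]
            for h in hits:
                ti, t = ts[h]
                ov = min(q.end, t.end) - max(q.start, t.start)
                if rule.qualifies(ov, len(q), len(t)):
                    out.append((qi, ti, ov))
    return out


def merge(intervals):
    """Merge strictly overlapping intervals; bookended intervals stay distinct."""
    _check_sorted(intervals, "merge input")
    merged: list[GenomicInterval] = []
    for iv in intervals:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(prev.chrom, prev.start,
                                         max(prev.end, iv.end))
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def covered_bp(intervals) -> int:
    """Total bp covered by a (possibly overlapping) interval set."""
    return sum(len(iv) for iv in merge(sorted(
        intervals, key=lambda iv: (iv.chrom, iv.start))))


def distance_to_nearest(query, anchors):
    """Midpoint distance from each query to its nearest anchor point.

    ``anchors`` is a list of (chrom, pos) points.  Queries on chromosomes
    with no anchor get ``None``.
    """
    pts: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in anchors:
        by_chrom[chrom].append(pos)
    for chrom, positions in by_chrom.items():
        pts[chrom] = np.sort(np.asarray(positions))
    out: list[int | None] = []
    for q in query:
        arr = pts.get(q.chrom)
        if arr is None:
            out.append(None)
            continue
        mid = q.midpoint
        i = int(np.searchsorted(arr, mid))
        best = min(
            (abs(mid - int(arr[j])) for j in (i - 1, i) if 0 <= j < len(arr)))
        out.append(best)
    return out


def make_windows(interval: GenomicInterval, n: int):
    """Tile ``interval`` into ``n`` contiguous windows (winnum convention).

    The first ``len mod n`` windows get the extra bp so window sizes differ
    by at most 1.  Window index is stored in ``name``.
    """
    length = len(interval)
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < n:
        raise ValueError(f"interval length {length} < number of windows {n}")
    base, extra = divmod(length, n)
    windows = []
    pos = interval.start
    for i in range(n):
        size = base + (1 if i < extra else 0)
        windows.append(GenomicInterval(interval.chrom, pos, pos + size,
                                       interval.strand, name=str(i + 1)))
        pos += size
    assert pos == interval.end
    return windows


def jaccard(set_a, set_b, mode: str = "bp") -> float:
    """Jaccard similarity of two merged interval sets.

    ``bp`` mode: intersecting bp / union bp.  ``element`` mode: components
    of the merged union containing members of both sets, over all union
    components (the anchor-matching convention used for loop anchors).
    """
    if not set_a and not set_b:
        raise ValueError("Jaccard of two empty sets is undefined")
    if mode == "bp":
        inter = sum(ov for _, _, ov in intersect(set_a, set_b, ANY_OVERLAP))
        union = covered_bp(list(set_a) + list(set_b))
        return inter / union
    if mode == "element":
        both = sorted(list(set_a) + list(set_b), key=lambda iv: (iv.chrom, iv.start))
        components = merge(both)
        in_a = {ci for _, ci, _ in intersect(sorted(set_a, key=lambda iv: (iv.chrom, iv.start)),
                                             components, ANY_OVERLAP)}
        in_b = {ci for _, ci, _ in intersect(sorted(set_b, key=lambda iv: (iv.chrom, iv.start)),
                                             components, ANY_OVERLAP)}
        return len(in_a & in_b) / len(components)
    raise ValueError(f"unknown Jaccard mode {mode!r}")


def overlaps_any(query, target, rule: OverlapRule = ANY_OVERLAP) -> np.ndarray:
    """Boolean flag per query: overlaps >= 1 target under ``rule``."""
    flags = np.zeros(len(query), dtype=bool)
    for qi, _, _ in intersect(query, target, rule):
        flags[qi] = True
    return flags
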