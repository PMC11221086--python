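"""Loop-anchor genotype comparison, loop classification, CTCF motif
orientation at anchor pairs, binned anchor profiles and DEG-loop linkage.

Anchor comparison pools both ends of every loop per genotype, merges them,
and matches merged anchors between genotypes by >= 1 bp overlap: KO-only
components are new loop anchors (NLA), WT-only are lost (LLA), and the
merged union of all matched anchors forms the unchanged set (ULA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import intersect, make_windows, merge, overlaps_any
from .models import ANY_OVERLAP, GenomicInterval, Loop, MotifHit
from .te_enrichment import promoter_of


@dataclass(frozen=True)
class AnchorClassification:
    nla: list
    lla: list
    ula: list
    jaccard: float


@dataclass(frozen=True)
class LoopClass:
    loop: Loop
    klass: str


@dataclass(frozen=True)
class OrientationCall:
    loop: Loop
    left_strand: str
    right_strand: str
    orientation: str


def _merged_anchors(loops):
    anchors = sorted(
        (a for lp in loops for a in (lp.anchorL, lp.anchorR)),
        key=lambda iv: (iv.chrom, iv.start))
    return merge(anchors)


def classify_anchors(wt_loops, ko_loops) -> AnchorClassification:
    """Split merged WT/KO loop anchors into NLA / LLA / ULA.

    Jaccard (element mode) = |ULA| / (|NLA| + |LLA| + |ULA|).
    """
    if not wt_loops or not ko_loops:
        raise ValueError("both genotypes need >= 1 loop")
    wt = _merged_anchors(wt_loops)
    ko = _merged_anchors(ko_loops)
    ko_matched = overlaps_any(ko, wt)
    wt_matched = overlaps_any(wt, ko)
    nla = [a for a, m in zip(ko, ko_matched) if not m]
    lla = [a for a, m in zip(wt, wt_matched) if not m]
    matched = sorted(
        [a for a, m in zip(ko, ko_matched) if m]
        + [a for a, m in zip(wt, wt_matched) if m],
        key=lambda iv: (iv.chrom, iv.start))
    ula = merge(matched)
    denom = len(nla) + len(lla) + len(ula)
    return AnchorClassification(nla, lla, ula,
                                len(ula) / denom if denom else float("nan"))


def _loop_hits(loops, components) -> np.ndarray:
    """Per-loop flag: >= 1 anchor overlaps >= 1 component (>= 1 bp)."""
    flags = np.zeros(len(loops), dtype=bool)
    if not components:
        return flags
    anchors = []
    owner = []
    for i, lp in enumerate(loops):
        anchors.extend((lp.anchorL, lp.anchorR))
        owner.extend((i, i))
    order = sorted(range(len(anchors)),
                   key=lambda k: (anchors[k].chrom, anchors[k].start))
    sorted_anchors = [anchors[k] for k in order]
    comp = sorted(components, key=lambda iv: (iv.chrom, iv.start))
    for qi, _, _ in intersect(sorted_anchors, comp, ANY_OVERLAP):
        flags[owner[order[qi]]] = True
    return flags


def classify_loops(wt_loops, ko_loops, cls: AnchorClassification):
    """KO loops become new (>= 1 anchor on an NLA component) or unchanged;
    WT loops with >= 1 anchor on an LLA component are lost.  WT loops whose
    anchors all persist are not emitted (they are the KO unchanged loops'
    counterparts)."""
    out: list[LoopClass] = []
    ko_new = _loop_hits(ko_loops, cls.nla)
    for lp, is_new in zip(ko_loops, ko_new):
        out.append(LoopClass(lp, "new" if is_new else "unchanged"))
    wt_lost = _loop_hits(wt_loops, cls.lla)
    for lp, is_lost in zip(wt_loops, wt_lost):
        if is_lost:
            out.append(LoopClass(lp, "lost"))
    return out


ORIENTATIONS = ("convergent", "divergent", "tandem")


def orientation_of(left: str, right: str) -> str:
    """CTCF motif orientation truth table for one anchor pair."""
    if left == "none" or right == "none":
        return "unclassified"
    if (left, right) == ("+", "-"):
        return "convergent"
    if (left, right) == ("-", "+"):
        return "divergent"
    return "tandem"


def orient_loops(loops, hits):
    """Orientation call per loop from per-anchor best motif hits.

    ``hits`` is a list of ``(left_hit, right_hit)`` :class:`MotifHit` pairs
    aligned with ``loops``; anchors whose best hit does not pass render the
    loop unclassified.  Returns (calls, summary) where the summary maps each
    orientation to its fraction of classified loops plus the unclassified
    count.
    """
    calls = []
    for lp, (hl, hr) in zip(loops, hits):
        ls = hl.strand if (hl is not None and hl.passes) else "none"
        rs = hr.strand if (hr is not None and hr.passes) else "none"
        calls.append(OrientationCall(lp, ls, rs, orientation_of(ls, rs)))
    n_classified = sum(c.orientation != "unclassified" for c in calls)
    summary = {
        o: (sum(c.orientation == o for c in calls) / n_classified
            if n_classified else float("nan"))
        for o in ORIENTATIONS
    }
    summary["n_classified"] = n_classified
    summary["n_unclassified"] = len(calls) - n_classified
    return calls, summary


def anchor_bin_profile(anchors, peaks, n_bins: int = 100) -> np.ndarray:
    """Mean per-bin peak count across anchors, each split into ``n_bins``.

    Each anchor is tiled with :func:`make_windows`; a bin's value is the
    number of peaks overlapping it by >= 1 bp; the profile is the mean over
    anchors per bin index.  Anchors shorter than ``n_bins`` are skipped.
    """
    peaks_sorted = sorted((getattr(p, "interval", p) for p in peaks),
                          key=lambda iv: (iv.chrom, iv.start))
    rows = []
    for anchor in anchors:
        if len(anchor) < n_bins:
            warnings.warn(
                f"anchor {anchor.chrom}:{anchor.start}-{anchor.end} shorter than "
                f"{n_bins} bins; skipped")
            continue
        bins = make_windows(anchor, n_bins)
        counts = np.zeros(n_bins)
        for bi, _, _ in intersect(bins, peaks_sorted, ANY_OVERLAP):
            counts[bi] += 1
        rows.append(counts)
    if not rows:
        return np.zeros(n_bins)
    return np.mean(rows, axis=0)


def link_deg_loops(degs, genes, classified_loops, ctcf_up_b2,
                   promoter_halfwidth: int = 3000, p_threshold: float = 0.05):
    """Genes whose promoters sit on anchors of B2-anchored new loops.

    ``degs`` is a DataFrame (gene, log2fc, p); DEGs are rows with
    p < ``p_threshold``.  A new loop is a B2_new_loop when >= 1 anchor
    overlaps a ``ctcf_up_b2`` region; a DEG is linked when its promoter
    (TSS +/- halfwidth) overlaps >= 1 anchor of such a loop.  Returns a
    list of (gene, loop, side) with side in {left, right}.
    """
    gene_by_name = {g.name: g for g in genes}
    deg_names = [str(r.gene) for r in degs.itertuples(index=False)
                 if float(r.p) < p_threshold]
    missing = [n for n in deg_names if n not in gene_by_name]
    if missing:
        warnings.warn(f"{len(missing)} DEGs absent from the gene model; skipped")
    deg_names = [n for n in deg_names if n in gene_by_name]

    b2 = sorted((getattr(t, "interval", t) for t in ctcf_up_b2),
                key=lambda iv: (iv.chrom, iv.start))
    new_loops = [lc.loop for lc in classified_loops if lc.klass == "new"]
    b2_new = [lp for lp, hit in zip(new_loops, _loop_hits(new_loops, b2)) if hit]

    links = []
    for name in deg_names:
        prom = promoter_of(gene_by_name[name], promoter_halfwidth)
        for lp in b2_new:
            for side, anchor in (("left", lp.anchorL), ("right", lp.anchorR)):
                if prom.overlap_bp(anchor) > 0:
                    links.append((name, lp, side))
    return links
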