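"""Hierarchical TE enrichment and genomic annotation of differential regions.

Enrichment compares a foreground (e.g. up-regulated peaks) against a
background that contains it (e.g. all detected peaks) with Fisher's exact
test, Benjamini-Hochberg adjusted across the categories of one hierarchy
level.  Two modes: element *count* (regions hitting >= 1 element of the
category) and cumulative *length* (bp of the distinct elements hit).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import intersect, overlaps_any
from .models import EnrichmentResult, GenomicInterval, OverlapRule

LEVELS = ("te_class", "sine_family", "b2_subtype")

#: hierarchy level -> (attribute holding the category, restriction)
_LEVEL_SPEC = {
    "te_class": ("te_class", None),
    "sine_family": ("te_family", lambda t: t.te_class == "SINE"),
    "b2_subtype": ("te_subtype", lambda t: t.te_family == "B2"),
}


def fisher_test(a: int, b: int, c: int, d: int):
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p); zero-margin odds ratios come back as 0 or inf.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("table cells must be non-negative")
    if all(x == 0 for x in cells):
        raise ValueError("all four cells are zero")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fold(obs_in, obs_tot, bg_in, bg_tot) -> float:
    if obs_tot == 0 or bg_tot == 0 or bg_in == 0:
        return float("nan") if obs_in == 0 else float("inf")
    return (obs_in / obs_tot) / (bg_in / bg_tot)


def _check_subset(foreground, background) -> None:
    bg = {(r.chrom, r.start, r.end) for r in background}
    for r in foreground:
        if (r.chrom, r.start, r.end) not in bg:
            raise ValueError(
                f"foreground region {r.chrom}:{r.start}-{r.end} absent from the "
                "background; the background must contain the foreground")


def _intervals(regions):
    """Accept plain intervals or DifferentialRegion-like objects."""
    return [getattr(r, "interval", r) for r in regions]


def enrich_te(diff_regions, all_regions, te, rule: OverlapRule,
              level: str, mode: str = "count"):
    """Enrichment of ``diff_regions`` vs the ``all_regions`` background across
    the categories of one TE hierarchy level.

    count mode cells: number of regions overlapping >= 1 element of the
    category vs not (foreground / background).  length mode cells:
    cumulative bp of the distinct elements of the category hit by the
    region set, vs bp of the hit elements of the level's other categories;
    bp cells enter Fisher's test as counts (fold enrichment is the primary
    length-mode readout).  A region hitting several elements of one category
    counts once; hitting several categories counts once per category.
    """
    if level not in _LEVEL_SPEC:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if mode not in ("count", "length"):
        raise ValueError("mode must be count or length")
    attr, restrict = _LEVEL_SPEC[level]
    elements = [t for t in te if restrict is None or restrict(t)]
    fg = sorted(_intervals(diff_regions), key=lambda r: (r.chrom, r.start))
    bg = sorted(_intervals(all_regions), key=lambda r: (r.chrom, r.start))
    _check_subset(fg, bg)

    te_ivs = sorted((t.interval for t in elements), key=lambda r: (r.chrom, r.start))
    cat_of = {(t.interval.chrom, t.interval.start, t.interval.end): getattr(t, attr)
              for t in elements}
    categories = sorted({getattr(t, attr) for t in elements})

    def hit_map(regions):
        """category -> (set of region indices, set of element keys) hit."""
        region_hits: dict[str, set[int]] = defaultdict(set)
        element_hits: dict[str, set[tuple]] = defaultdict(set)
        for qi, ti, _ in intersect(regions, te_ivs, rule):
            key = (te_ivs[ti].chrom, te_ivs[ti].start, te_ivs[ti].end)
            cat = cat_of[key]
            region_hits[cat].add(qi)
            element_hits[cat].add(key)
        return region_hits, element_hits

    fg_r, fg_e = hit_map(fg)
    bg_r, bg_e = hit_map(bg)

    rows = []
    for cat in categories:
        if mode == "count":
            a = len(fg_r.get(cat, ()))
            b = len(fg) - a
            c = len(bg_r.get(cat, ()))
            d = len(bg) - c
        else:
            def bp(hits):
                return int(sum(k[2] - k[1] for k in hits))
            a = bp(fg_e.get(cat, ()))
            b = int(sum(bp(v) for k, v in fg_e.items() if k != cat))
            c = bp(bg_e.get(cat, ()))
            d = int(sum(bp(v) for k, v in bg_e.items() if k != cat))
        fold = _fold(a, a + b, c, c + d)
        if (a, b, c, d) == (0, 0, 0, 0):
            p = 1.0
        else:
            _, p = fisher_test(a, b, c, d)
        rows.append((cat, a, b, c, d, fold, p))

    padj = bh_adjust([r[6] for r in rows]) if rows else []
    return [
        EnrichmentResult(level, cat, mode, a, b, c, d, fold, p, float(q))
        for (cat, a, b, c, d, fold, p), q in zip(rows, padj)
    ]


def tss_of(gene: GenomicInterval) -> int:
    """Strand-aware transcription start site (start for +, end for -)."""
    if gene.strand == "+":
        return gene.start
    if gene.strand == "-":
        return gene.end
    raise ValueError(f"gene {gene.name or gene.chrom} lacks a strand")


def promoter_of(gene: GenomicInterval, halfwidth: int = 3000) -> GenomicInterval:
    """Promoter window TSS +/- halfwidth (clipped at 0), half-open."""
    tss = tss_of(gene)
    return GenomicInterval(gene.chrom, max(0, tss - halfwidth), tss + halfwidth,
                           gene.strand, name=gene.name)


ANNOTATION_LABELS = ("promoter", "gene_body", "intergenic")


def annotate_regions(regions, genes, promoter_halfwidth: int = 3000):
    """Label each region promoter / gene_body / intergenic.

    Promoter = overlap with TSS +/- halfwidth of any gene; gene_body =
    overlap with a gene span but no promoter window; precedence
    promoter > gene_body > intergenic.  Overlap is >= 1 bp.
    """
    base = _intervals(regions)
    order = sorted(range(len(base)), key=lambda i: (base[i].chrom, base[i].start))
    ivs = [base[i] for i in order]
    promoters = sorted((promoter_of(g, promoter_halfwidth) for g in genes),
                       key=lambda r: (r.chrom, r.start))
    bodies = sorted(genes, key=lambda r: (r.chrom, r.start))
    in_prom = overlaps_any(ivs, promoters)
    in_body = overlaps_any(ivs, bodies)
    labels = [""] * len(regions)
    for sorted_i, orig_i in enumerate(order):
        if in_prom[sorted_i]:
            labels[orig_i] = "promoter"
        elif in_body[sorted_i]:
            labels[orig_i] = "gene_body"
        else:
            labels[orig_i] = "intergenic"
    return labels


def enrich_annotation(foreground, background, genes, promoter_halfwidth: int = 3000):
    """Genomic-annotation enrichment of foreground vs background regions."""
    if not background:
        raise ValueError("background is empty")
    _check_subset(_intervals(foreground), _intervals(background))
    fg_labels = annotate_regions(foreground, genes, promoter_halfwidth)
    bg_labels = annotate_regions(background, genes, promoter_halfwidth)
    rows = []
    for label in ANNOTATION_LABELS:
        a = sum(l == label for l in fg_labels)
        b = len(fg_labels) - a
        c = sum(l == label for l in bg_labels)
        d = len(bg_labels) - c
        fold = _fold(a, a + b, c, c + d)
        p = 1.0 if (a, b, c, d) == (0, 0, 0, 0) else fisher_test(a, b, c, d)[1]
        rows.append((label, a, b, c, d, fold, p))
    padj = bh_adjust([r[6] for r in rows])
    return [
        EnrichmentResult("genomic_annotation", label, "count", a, b, c, d,
                         fold, p, float(q))
        for (label, a, b, c, d, fold, p), q in zip(rows, padj)
    ]


def enrichment_to_frame(results):
    import pandas as pd

    return pd.DataFrame(
        [(r.level, r.category, r.mode, r.observed_in, r.observed_out,
          r.background_in, r.background_out, r.fold_enrichment, r.p, r.p_adj)
         for r in results],
        columns=["level", "category", "mode", "observed_in", "observed_out",
                 "background_in", "background_out", "fold_enrichment", "p", "p_adj"],
    )
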