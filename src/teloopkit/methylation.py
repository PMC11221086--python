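"""CpG filtering, DMR calling and methylation/accessibility quadrant integration.

DMRs are called from a per-CpG pooled-proportion difference (KO - WT):
candidate CpGs fall in the empirical quantile tails of that statistic,
same-sign candidates within ``max_gap`` bp are grouped, and candidate
regions become DMRs when they contain at least ``min_cpg`` CpGs, have an
absolute mean difference of at least ``min_abs_diff``, and lie on an
autosome.  This replaces the kernel-smoothed t-statistic of the bsseq
workflow with the same candidate-selection and filtering logic; the
simplification is deliberate and documented in the methods note.
"""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np

from .intervals import intersect, overlaps_any
from .models import (
    DMR,
    ANY_OVERLAP,
    CpGRecord,
    DifferentialRegion,
    GenomicInterval,
    OverlapRule,
    QuadrantRecord,
)
from .te_enrichment import fisher_test

DEFAULT_AUTOSOME_EXCLUDE = frozenset({"chrX", "chrY", "chrM"})


def _group_samples(group_map: dict[str, str]):
    wt = sorted(s for s, g in group_map.items() if g == "WT")
    ko = sorted(s for s, g in group_map.items() if g == "KO")
    if not wt or not ko:
        raise ValueError("group map must name >= 1 WT and >= 1 KO sample")
    return wt, ko


def filter_cpgs(records, group_map: dict[str, str]):
    """Retain CpGs covered by >= 2 reads in >= 1 sample of each group."""
    wt, ko = _group_samples(group_map)
    out = []
    for r in records:
        cov_wt = max((r.samples[s][1] for s in wt if s in r.samples), default=0)
        cov_ko = max((r.samples[s][1] for s in ko if s in r.samples), default=0)
        if cov_wt >= 2 and cov_ko >= 2:
            out.append(r)
    return out


def pooled_diff(record: CpGRecord, wt, ko) -> float:
    """Pooled KO proportion minus pooled WT proportion at one CpG."""
    def pool(samples):
        m = sum(record.samples[s][0] for s in samples if s in record.samples)
        t = sum(record.samples[s][1] for s in samples if s in record.samples)
        return m / t if t else np.nan
    return pool(ko) - pool(wt)


def pooled_mean(record: CpGRecord) -> float:
    m = sum(v[0] for v in record.samples.values())
    t = sum(v[1] for v in record.samples.values())
    return m / t if t else np.nan


def call_dmrs(records, group_map: dict[str, str], *,
              q_low: float = 0.01, q_high: float = 0.99,
              max_gap: int = 300, min_cpg: int = 3,
              min_abs_diff: float = 0.1,
              autosomes: frozenset[str] | None = None):
    """Call DMRs from filtered CpG records.

    ``autosomes`` gives the allowed chromosomes; by default every
    chromosome except chrX/chrY/chrM is accepted.
    """
    wt, ko = _group_samples(group_map)
    records = sorted(records, key=lambda r: (r.chrom, r.pos))
    if len(records) < 10:
        raise ValueError(
            f"only {len(records)} retained CpGs; quantile cutoffs are unstable "
            "below 10")
    d = np.array([pooled_diff(r, wt, ko) for r in records])
    lo, hi = np.quantile(d, [q_low, q_high])
    candidate = (d < lo) | (d > hi)

    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, r in enumerate(records):
        if candidate[i]:
            by_chrom[r.chrom].append(i)

    dmrs: list[DMR] = []
    for chrom in sorted(by_chrom):
        idxs = by_chrom[chrom]
        runs: list[list[int]] = []
        for i in idxs:
            if (runs
                    and records[i].pos - records[runs[-1][-1]].pos <= max_gap
                    and (d[i] < 0) == (d[runs[-1][-1]] < 0)):
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            mean_diff = float(d[run].mean())
            if len(run) < min_cpg or abs(mean_diff) < min_abs_diff:
                continue
            if autosomes is not None:
                if chrom not in autosomes:
                    continue
            elif chrom in DEFAULT_AUTOSOME_EXCLUDE:
                continue
            first, last = records[run[0]], records[run[-1]]
            avg = float(np.mean([pooled_mean(records[i]) for i in run]))
            dmrs.append(DMR(
                GenomicInterval(chrom, first.pos, last.pos + 1),
                n_cpg=len(run), mean_diff=mean_diff, avg_meth=avg,
                status="hypo" if mean_diff < 0 else "hyper"))
    dmrs.sort(key=lambda x: (x.interval.chrom, x.interval.start))
    return dmrs


def quadrant_of(log2fc: float, mean_diff: float) -> int:
    if log2fc > 0:
        return 1 if mean_diff >= 0 else 4
    return 2 if mean_diff >= 0 else 3


def quadrant_integration(dmrs, atac_diff, b2_elements,
                         rule: OverlapRule = OverlapRule()):
    """Pair DMRs with significant differential peaks and test B2 vs Q4.

    One record per (DMR, peak) pair with >= 1 bp overlap.  ``is_b2`` means
    either member overlaps a B2 element under ``rule``.  Returns the record
    list plus a Fisher result on {B2, non-B2} x {Q4, not Q4}: dict with the
    2x2 cells, fold enrichment of Q4 membership among B2 pairs relative to
    all pairs, odds ratio and p.
    """
    sig_atac = [a for a in atac_diff if a.direction != "ns"]
    dmr_ivs = sorted((x.interval for x in dmrs), key=lambda r: (r.chrom, r.start))
    dmr_order = sorted(range(len(dmrs)),
                       key=lambda i: (dmrs[i].interval.chrom, dmrs[i].interval.start))
    atac_ivs = sorted((a.interval for a in sig_atac),
                      key=lambda r: (r.chrom, r.start))
    atac_order = sorted(range(len(sig_atac)),
                        key=lambda i: (sig_atac[i].interval.chrom,
                                       sig_atac[i].interval.start))
    b2_ivs = sorted((getattr(t, "interval", t) for t in b2_elements),
                    key=lambda r: (r.chrom, r.start))
    dmr_b2 = overlaps_any(dmr_ivs, b2_ivs, rule)
    atac_b2 = overlaps_any(atac_ivs, b2_ivs, rule)

    pairs = intersect(dmr_ivs, atac_ivs, ANY_OVERLAP)
    if not pairs:
        warnings.warn("no overlapping (DMR, peak) pairs")
        return [], None
    out: list[QuadrantRecord] = []
    for qi, ti, _ in pairs:
        dmr = dmrs[dmr_order[qi]]
        atac = sig_atac[atac_order[ti]]
        out.append(QuadrantRecord(
            dmr=dmr, atac=atac,
            quadrant=quadrant_of(atac.log2fc, dmr.mean_diff),
            is_b2=bool(dmr_b2[qi] or atac_b2[ti]),
            is_significant=True))

    a = sum(1 for r in out if r.is_b2 and r.quadrant == 4)
    b = sum(1 for r in out if r.is_b2 and r.quadrant != 4)
    c = sum(1 for r in out if not r.is_b2 and r.quadrant == 4)
    d = sum(1 for r in out if not r.is_b2 and r.quadrant != 4)
    n_b2, n_all = a + b, len(out)
    q4_all = a + c
    fold = (a / n_b2) / (q4_all / n_all) if n_b2 and q4_all else float("nan")
    odds, p = fisher_test(a, b, c, d)
    fisher = {"b2_q4": a, "b2_other": b, "nonb2_q4": c, "nonb2_other": d,
              "fold_enrichment": fold, "odds_ratio": odds, "p": p}
    return out, fisher


def dmrs_to_frame(dmrs):
    import pandas as pd

    return pd.DataFrame(
        [(x.interval.chrom, x.interval.start, x.interval.end, x.n_cpg,
          x.mean_diff, x.avg_meth, x.status) for x in dmrs],
        columns=["chrom", "start", "end", "n_cpg", "mean_diff", "avg_meth",
                 "status"],
    )
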