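"""Self-consistent synthetic dataset with ground truth for every stage.

The generator builds a toy multi-chromosome genome carrying a TE annotation
with realistic class/length structure, plants every downstream signal —
up-regulated accessibility peaks enriched on one B2 subtype at a configured
odds ratio, CTCF-like motif instances at controlled rates and strands,
hypo/hyper-methylated CpG runs with binomial read noise, chromatin loops
whose KO-specific anchors sit on motif-bearing B2 elements with a
configured orientation mix, and DEGs whose promoters sit on anchors of
B2-anchored new loops — and records the truth label of every planted
record.  All randomness flows from one seeded generator; the same config
and seed reproduce the bundle byte for byte.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomic_io
from .models import (
    DifferentialRegion,
    CpGRecord,
    GenomicInterval,
    Loop,
    PWM,
    TEElement,
    classify_direction,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: near-one-hot CTCF-like motif; deliberately non-palindromic so the strand
#: of a planted instance is unambiguous.
CTCF_CONSENSUS = "CCACCAGGTGGC"


def default_ctcf_pwm(consensus: str = CTCF_CONSENSUS,
                     match_p: float = 0.91) -> PWM:
    """A strongly informative PWM around ``consensus``."""
    off = (1.0 - match_p) / 3.0
    probs = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = match_p
    return PWM(probs)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle (defaults are the ones the
    test-suite and the acceptance analyses run under)."""

    seed: int = 42
    chrom_sizes: dict = field(default_factory=lambda: {
        "chr1": 5_000_000, "chr2": 5_000_000})

    # --- TE annotation ---------------------------------------------------
    n_te: int = 4000
    te_class_mix: dict = field(default_factory=lambda: {
        "SINE": 0.55, "LINE": 0.20, "LTR": 0.15, "DNA": 0.10})
    sine_family_mix: dict = field(default_factory=lambda: {
        "B2": 0.50, "Alu": 0.30, "MIR": 0.20})
    b2_subtype_mix: dict = field(default_factory=lambda: {
        "B3": 0.35, "B3A": 0.25, "B2_Mm2": 0.20, "B2_Mm1t": 0.10,
        "B2_Mm1a": 0.10})
    te_length_ranges: dict = field(default_factory=lambda: {
        "SINE": (120, 220), "LINE": (500, 4000), "LTR": (300, 3000),
        "DNA": (200, 1000)})

    # --- differential peaks ----------------------------------------------
    target_subtype: str = "B3"
    n_peaks_on_target: int = 150
    n_peaks_on_other_b2: int = 600
    n_peaks_on_other_te: int = 300
    n_peaks_background: int = 450
    peak_length_range: tuple = (300, 800)
    up_rate_other: float = 0.08
    up_odds_ratio: float = 5.0
    down_rate_of_rest: float = 0.10

    # --- motifs -----------------------------------------------------------
    motif_rate_target: float = 0.60
    motif_rate_other_b2: float = 0.10

    # --- loops ------------------------------------------------------------
    n_loops_shared: int = 170
    n_loops_wt_specific: int = 80
    n_loops_ko_specific: int = 80
    anchor_width: int = 5_000
    loop_span_range: tuple = (100_000, 1_000_000)
    convergent_frac: float = 0.70
    divergent_frac: float = 0.10

    # --- methylation -------------------------------------------------------
    n_dmr_hypo_b2: int = 40
    n_dmr_hypo_other: int = 10
    n_dmr_hyper: int = 10
    dmr_delta: float = 0.30
    dmr_cpg_range: tuple = (12, 18)
    dmr_spacing_range: tuple = (30, 60)
    n_null_cpg: int = 75_000
    coverage: int = 10
    base_meth_ab: tuple = (34.0, 6.0)
    samples: dict = field(default_factory=lambda: {
        "WT_1": "WT", "WT_2": "WT", "KO_1": "KO", "KO_2": "KO"})

    # --- expression --------------------------------------------------------
    n_genes: int = 200
    n_linked_degs: int = 12
    n_other_degs: int = 20
    gene_length_range: tuple = (2_000, 20_000)
    edge_margin: int = 10_000

    @property
    def up_rate_target(self) -> float:
        odds = self.up_odds_ratio * self.up_rate_other / (1 - self.up_rate_other)
        return odds / (1 + odds)


@dataclass
class TruthLabels:
    peak_direction: list
    peak_target_element: list          # per peak: target-element index or None
    motif_elements: dict               # element index -> planted strand
    ko_specific_loops: list            # (loop index in KO list, orientation)
    dmr_regions: list                  # (chrom, start, end, status, on_b2)
    linked_genes: list
    deg_genes: list
    realized: dict


@dataclass
class Bundle:
    config: SyntheticConfig
    genome: dict
    te: list
    genes: list
    atac_diff: list
    cpg: list
    group_map: dict
    pwm: PWM
    wt_loops: list
    ko_loops: list
    degs: pd.DataFrame
    ctcf_up_b2: list
    track: pd.DataFrame
    truth: TruthLabels


class _Registry:
    """Per-chromosome occupied-interval registry for non-overlapping placement."""

    def __init__(self, chroms):
        self._occ = {c: ([], []) for c in chroms}  # sorted starts, ends

    def free(self, chrom: str, start: int, end: int) -> bool:
        starts, ends = self._occ[chrom]
        i = bisect.bisect_left(starts, end)
        return not (i > 0 and ends[i - 1] > start)

    def add(self, chrom: str, start: int, end: int) -> None:
        starts, ends = self._occ[chrom]
        i = bisect.bisect_left(starts, end)
        starts.insert(i, start)
        ends.insert(i, end)

    def try_add(self, chrom: str, start: int, end: int) -> bool:
        if not self.free(chrom, start, end):
            return False
        self.add(chrom, start, end)
        return True


def _exact_count_mask(rng, n: int, rate: float) -> np.ndarray:
    """Boolean mask with exactly round(n * rate) True entries, shuffled."""
    k = int(round(n * rate))
    mask = np.zeros(n, dtype=bool)
    mask[:k] = True
    rng.shuffle(mask)
    return mask


def _place_elements(rng, cfg, registry):
    chroms = sorted(cfg.chrom_sizes)
    classes = []
    for cls, frac in sorted(cfg.te_class_mix.items()):
        classes.extend([cls] * int(round(cfg.n_te * frac)))
    classes = classes[:cfg.n_te]
    rng.shuffle(classes)
    demand = sum(np.mean(cfg.te_length_ranges[c]) for c in classes)
    if demand > 0.6 * sum(cfg.chrom_sizes.values()):
        raise ValueError("TE bp demand exceeds 60% of the genome; infeasible config")
    placed = []
    for cls in classes:
        lo, hi = cfg.te_length_ranges[cls]
        for _ in range(1000):
            length = int(rng.integers(lo, hi + 1))
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(cfg.edge_margin,
                                     cfg.chrom_sizes[chrom] - cfg.edge_margin - length))
            if registry.try_add(chrom, start, start + length):
                placed.append((chrom, start, start + length, cls))
                break
        else:
            raise ValueError("could not place a TE after 1000 attempts")
    placed.sort()
    return placed


def _assign_hierarchy(rng, cfg, placed):
    other_families = {"LINE": ("L1", ("L1Md_A", "L1Md_T")),
                      "LTR": ("ERVK", ("IAPEz", "RLTR10")),
                      "DNA": ("hAT", ("Charlie1", "Tigger1"))}
    sine_idx = [i for i, p in enumerate(placed) if p[3] == "SINE"]
    fams = []
    for fam, frac in sorted(cfg.sine_family_mix.items()):
        fams.extend([fam] * int(round(len(sine_idx) * frac)))
    fams = (fams + ["B2"] * len(sine_idx))[:len(sine_idx)]
    rng.shuffle(fams)
    b2_local = [j for j, f in enumerate(fams) if f == "B2"]
    subs = []
    for sub, frac in sorted(cfg.b2_subtype_mix.items()):
        subs.extend([sub] * int(round(len(b2_local) * frac)))
    subs = (subs + [cfg.target_subtype] * len(b2_local))[:len(b2_local)]
    rng.shuffle(subs)
    sub_of = dict(zip(b2_local, subs))

    sine_rank = {i: j for j, i in enumerate(sine_idx)}
    elements = []
    for i, (chrom, start, end, cls) in enumerate(placed):
        if cls == "SINE":
            j = sine_rank[i]
            fam = fams[j]
            sub = sub_of.get(j, fam)  # non-B2 SINEs: subtype = family
        else:
            fam, subtypes = other_families[cls]
            sub = subtypes[int(rng.integers(len(subtypes)))]
        elements.append(TEElement(GenomicInterval(chrom, start, end), cls, fam, sub))
    return elements


def _pair_loops(rng, cfg, candidates, anchor_registry):
    """Pair motif-bearing target elements into KO-specific loops."""
    w = cfg.anchor_width
    span_lo, span_hi = cfg.loop_span_range
    pool = list(candidates)
    rng.shuffle(pool)

    def anchor_of(el):
        c = el.interval.midpoint
        return el.interval.chrom, c - w // 2, c + w // 2

    pairs = []
    used = set()
    for ei, el in pool:
        if ei in used or not anchor_registry.free(*anchor_of(el)):
            continue
        c1 = el.interval.midpoint
        mates = [
            (ej, em) for ej, em in pool
            if ej not in used and ej != ei
            and em.interval.chrom == el.interval.chrom
            and span_lo <= abs(em.interval.midpoint - c1) <= span_hi
            and anchor_registry.free(*anchor_of(em))
            and abs(em.interval.midpoint - c1) >= w
        ]
        if not mates:
            continue
        ej, em = mates[int(rng.integers(len(mates)))]
        used.update((ei, ej))
        anchor_registry.add(*anchor_of(el))
        anchor_registry.add(*anchor_of(em))
        if em.interval.midpoint < c1:
            pairs.append(((ej, em), (ei, el)))
        else:
            pairs.append(((ei, el), (ej, em)))
        if len(pairs) == cfg.n_loops_ko_specific:
            break
    if len(pairs) < cfg.n_loops_ko_specific:
        raise ValueError(
            f"only {len(pairs)} KO-specific loops could be placed; "
            "increase n_te or motif_rate_target")
    return pairs


def _random_loop(rng, cfg, registry):
    chroms = sorted(cfg.chrom_sizes)
    w = cfg.anchor_width
    span_lo, span_hi = cfg.loop_span_range
    for _ in range(1000):
        chrom = chroms[int(rng.integers(len(chroms)))]
        span = int(rng.integers(span_lo, span_hi + 1))
        max_start = cfg.chrom_sizes[chrom] - cfg.edge_margin - span - w
        if max_start <= cfg.edge_margin:
            continue
        s1 = int(rng.integers(cfg.edge_margin, max_start))
        s2 = s1 + span
        if registry.free(chrom, s1, s1 + w) and registry.free(chrom, s2, s2 + w):
            registry.add(chrom, s1, s1 + w)
            registry.add(chrom, s2, s2 + w)
            return (GenomicInterval(chrom, s1, s1 + w),
                    GenomicInterval(chrom, s2, s2 + w))
    raise ValueError("could not place a random loop after 1000 attempts")


def generate(config: SyntheticConfig | None = None) -> Bundle:
    """Generate the full synthetic bundle with truth labels."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    chroms = sorted(cfg.chrom_sizes)
    pwm = default_ctcf_pwm()

    te_registry = _Registry(chroms)
    placed = _place_elements(rng, cfg, te_registry)
    te = _assign_hierarchy(rng, cfg, placed)

    target_idx = [i for i, t in enumerate(te)
                  if t.te_family == "B2" and t.te_subtype == cfg.target_subtype]
    other_b2_idx = [i for i, t in enumerate(te)
                    if t.te_family == "B2" and t.te_subtype != cfg.target_subtype]

    # --- motif planting ----------------------------------------------------
    motif_elements: dict[int, str] = {}
    tgt_mask = _exact_count_mask(rng, len(target_idx), cfg.motif_rate_target)
    for i, has in zip(target_idx, tgt_mask):
        if has:
            motif_elements[i] = "?"  # strand decided below
    oth_mask = _exact_count_mask(rng, len(other_b2_idx), cfg.motif_rate_other_b2)
    for i, has in zip(other_b2_idx, oth_mask):
        if has:
            motif_elements[i] = "+" if rng.random() < 0.5 else "-"

    # --- loops -------------------------------------------------------------
    anchor_registry = _Registry(chroms)
    motif_targets = [(i, te[i]) for i in target_idx if i in motif_elements]
    pairs = _pair_loops(rng, cfg, motif_targets, anchor_registry)

    n_ko = cfg.n_loops_ko_specific
    n_conv = int(round(n_ko * cfg.convergent_frac))
    n_div = int(round(n_ko * cfg.divergent_frac))
    orientations = (["convergent"] * n_conv + ["divergent"] * n_div
                    + ["tandem"] * (n_ko - n_conv - n_div))
    rng.shuffle(orientations)

    w = cfg.anchor_width
    ko_specific_loops = []
    ko_loop_truth = []
    for ((ei, el), (ej, er)), orient in zip(pairs, orientations):
        if orient == "convergent":
            sl, sr = "+", "-"
        elif orient == "divergent":
            sl, sr = "-", "+"
        else:
            sl = sr = "+" if rng.random() < 0.5 else "-"
        motif_elements[ei] = sl
        motif_elements[ej] = sr
        cl, cr = el.interval.midpoint, er.interval.midpoint
        loop = Loop(GenomicInterval(el.interval.chrom, cl - w // 2, cl + w // 2),
                    GenomicInterval(er.interval.chrom, cr - w // 2, cr + w // 2),
                    "KO")
        ko_specific_loops.append(loop)
        ko_loop_truth.append(orient)
    # unused motif-bearing target elements get a random strand
    for i, s in motif_elements.items():
        if s == "?":
            motif_elements[i] = "+" if rng.random() < 0.5 else "-"

    shared = []
    for _ in range(cfg.n_loops_shared):
        a, b = _random_loop(rng, cfg, anchor_registry)
        shared.append((a, b))
    wt_only = []
    for _ in range(cfg.n_loops_wt_specific):
        a, b = _random_loop(rng, cfg, anchor_registry)
        wt_only.append((a, b))

    wt_loops = ([Loop(a, b, "WT") for a, b in shared]
                + [Loop(a, b, "WT") for a, b in wt_only])
    ko_loops = [Loop(a, b, "KO") for a, b in shared] + ko_specific_loops

    # --- genome sequence with planted motifs --------------------------------
    genome_bytes = {}
    for chrom in chroms:
        codes = rng.integers(0, 4, size=cfg.chrom_sizes[chrom])
        genome_bytes[chrom] = bytearray(_BASES[codes].tobytes())
    from .motif import revcomp  # local import to avoid a cycle at module load

    consensus = pwm.consensus
    for i, strand in motif_elements.items():
        iv = te[i].interval
        start = iv.midpoint - len(consensus) // 2
        inst = consensus if strand == "+" else revcomp(consensus)
        genome_bytes[iv.chrom][start:start + len(consensus)] = inst.encode()
    genome = {c: bytes(b).decode("ascii") for c, b in genome_bytes.items()}

    # --- differential peaks --------------------------------------------------
    def peak_on(center: int, chrom: str) -> GenomicInterval:
        length = int(rng.integers(*cfg.peak_length_range))
        start = max(0, center - length // 2)
        return GenomicInterval(chrom, start, start + length)

    peak_ivs: list[GenomicInterval] = []
    peak_src: list[int | None] = []  # target element index, or None
    tgt_for_peaks = list(rng.choice(target_idx, size=cfg.n_peaks_on_target,
                                    replace=False))
    for i in tgt_for_peaks:
        iv = te[i].interval
        peak_ivs.append(peak_on(iv.midpoint, iv.chrom))
        peak_src.append(i)
    for i in rng.choice(other_b2_idx, size=cfg.n_peaks_on_other_b2,
                        replace=False):
        iv = te[int(i)].interval
        peak_ivs.append(peak_on(iv.midpoint, iv.chrom))
        peak_src.append(None)
    non_b2 = [i for i in range(len(te)) if te[i].te_family != "B2"]
    for i in rng.choice(non_b2, size=cfg.n_peaks_on_other_te, replace=False):
        iv = te[int(i)].interval
        peak_ivs.append(peak_on(iv.midpoint, iv.chrom))
        peak_src.append(None)
    for _ in range(cfg.n_peaks_background):
        chrom = chroms[int(rng.integers(len(chroms)))]
        center = int(rng.integers(cfg.edge_margin,
                                  cfg.chrom_sizes[chrom] - cfg.edge_margin))
        peak_ivs.append(peak_on(center, chrom))
        peak_src.append(None)

    n_tgt = cfg.n_peaks_on_target
    n_rest = len(peak_ivs) - n_tgt
    up_mask = np.concatenate([
        _exact_count_mask(rng, n_tgt, cfg.up_rate_target),
        _exact_count_mask(rng, n_rest, cfg.up_rate_other)])
    directions = []
    down_pool = np.flatnonzero(~up_mask)
    down_sel = set(down_pool[_exact_count_mask(rng, len(down_pool),
                                               cfg.down_rate_of_rest)].tolist())
    for k in range(len(peak_ivs)):
        if up_mask[k]:
            directions.append("up")
        elif k in down_sel:
            directions.append("down")
        else:
            directions.append("ns")

    atac_diff = []
    for iv, direction in zip(peak_ivs, directions):
        if direction == "up":
            lfc = float(rng.uniform(0.7, 3.0))
            fdr = float(rng.uniform(1e-6, 0.049))
        elif direction == "down":
            lfc = float(rng.uniform(-3.0, -0.7))
            fdr = float(rng.uniform(1e-6, 0.049))
        else:
            lfc = float(rng.uniform(-0.5, 0.5))
            fdr = float(rng.uniform(0.05, 1.0))
        assert classify_direction(lfc, fdr) == direction
        atac_diff.append(DifferentialRegion(iv, lfc, fdr, direction))

    # --- methylation ----------------------------------------------------------
    up_target_peaks = [k for k in range(n_tgt) if directions[k] == "up"]
    up_bg_peaks = [k for k in range(len(peak_ivs))
                   if directions[k] == "up" and peak_src[k] is None]
    down_peaks = [k for k in range(len(peak_ivs)) if directions[k] == "down"]
    dmr_spec = []  # (center chrom, center pos, delta sign, on_b2)
    for k in rng.choice(up_target_peaks, size=cfg.n_dmr_hypo_b2, replace=False):
        iv = peak_ivs[int(k)]
        dmr_spec.append((iv.chrom, iv.midpoint, -1, True))
    for k in rng.choice(up_bg_peaks, size=cfg.n_dmr_hypo_other, replace=False):
        iv = peak_ivs[int(k)]
        dmr_spec.append((iv.chrom, iv.midpoint, -1, False))
    for k in rng.choice(down_peaks, size=cfg.n_dmr_hyper, replace=False):
        iv = peak_ivs[int(k)]
        dmr_spec.append((iv.chrom, iv.midpoint, +1, False))

    a_b, b_b = cfg.base_meth_ab
    sample_names = sorted(cfg.samples)
    wt_samples = [s for s in sample_names if cfg.samples[s] == "WT"]
    ko_samples = [s for s in sample_names if cfg.samples[s] == "KO"]

    cpg_positions: dict[str, dict[int, tuple[float, float]]] = {c: {} for c in chroms}
    dmr_truth = []
    for chrom, center, sign, on_b2 in dmr_spec:
        n_cpg = int(rng.integers(*cfg.dmr_cpg_range))
        gaps = rng.integers(cfg.dmr_spacing_range[0], cfg.dmr_spacing_range[1] + 1,
                            size=n_cpg - 1)
        span = int(gaps.sum())
        pos = center - span // 2
        # hyper regions start from a low-methylation baseline (CpG-island
        # like) so the planted +delta is not clipped at 1
        p_wt = float(rng.beta(a_b, b_b)) if sign < 0 else float(rng.beta(b_b, a_b))
        p_ko = float(np.clip(p_wt + sign * cfg.dmr_delta, 0.02, 0.98))
        positions = [pos]
        for g in gaps:
            positions.append(positions[-1] + int(g))
        for p in positions:
            cpg_positions[chrom][p] = (p_wt, p_ko)
        dmr_truth.append((chrom, positions[0], positions[-1] + 1,
                          "hypo" if sign < 0 else "hyper", on_b2))

    n_placed = 0
    while n_placed < cfg.n_null_cpg:
        chrom = chroms[int(rng.integers(len(chroms)))]
        p = int(rng.integers(100, cfg.chrom_sizes[chrom] - 100))
        if p in cpg_positions[chrom]:
            continue
        # background methylation is bimodal: mostly high, ~10% low (islands)
        if rng.random() < 0.9:
            pv = float(rng.beta(a_b, b_b))
        else:
            pv = float(rng.beta(b_b, a_b))
        cpg_positions[chrom][p] = (pv, pv)
        n_placed += 1

    cpg_records = []
    for chrom in chroms:
        pos_sorted = sorted(cpg_positions[chrom])
        p_wt_arr = np.array([cpg_positions[chrom][p][0] for p in pos_sorted])
        p_ko_arr = np.array([cpg_positions[chrom][p][1] for p in pos_sorted])
        meth = {}
        for s in wt_samples:
            meth[s] = rng.binomial(cfg.coverage, p_wt_arr)
        for s in ko_samples:
            meth[s] = rng.binomial(cfg.coverage, p_ko_arr)
        for k, p in enumerate(pos_sorted):
            counts = {s: (int(meth[s][k]), cfg.coverage)
                      for s in sample_names}
            cpg_records.append(CpGRecord(chrom, p, counts))

    # --- genes and DEGs -------------------------------------------------------
    genes = []
    linked = []
    loop_choice = rng.choice(len(ko_specific_loops), size=cfg.n_linked_degs,
                             replace=False)
    for gi, li in enumerate(loop_choice):
        lp = ko_specific_loops[int(li)]
        anchor = lp.anchorL if rng.random() < 0.5 else lp.anchorR
        tss = int(rng.integers(anchor.start + w // 4, anchor.end - w // 4))
        length = int(rng.integers(*cfg.gene_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene_linked_{gi + 1:03d}"
        if strand == "+":
            g = GenomicInterval(anchor.chrom, tss, tss + length, strand, name)
        else:
            g = GenomicInterval(anchor.chrom, max(0, tss - length), tss, strand, name)
        genes.append(g)
        linked.append(name)

    ko_anchor_ivs = [a for lp in ko_specific_loops for a in (lp.anchorL, lp.anchorR)]

    def far_from_new_anchors(chrom: str, tss: int, margin: int = 20_000) -> bool:
        return all(a.chrom != chrom or not (a.start - margin <= tss < a.end + margin)
                   for a in ko_anchor_ivs)

    gi = 0
    while len(genes) < cfg.n_genes:
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(*cfg.gene_length_range))
        tss_lo = cfg.edge_margin + length
        tss_hi = cfg.chrom_sizes[chrom] - cfg.edge_margin - length
        tss = int(rng.integers(tss_lo, tss_hi))
        if not far_from_new_anchors(chrom, tss):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gi += 1
        name = f"gene_{gi:03d}"
        if strand == "+":
            genes.append(GenomicInterval(chrom, tss, tss + length, strand, name))
        else:
            genes.append(GenomicInterval(chrom, tss - length, tss, strand, name))

    other_names = [g.name for g in genes if g.name not in set(linked)]
    other_degs = list(rng.choice(other_names, size=cfg.n_other_degs, replace=False))
    deg_rows = []
    for g in genes:
        is_deg = g.name in set(linked) or g.name in set(other_degs)
        p = float(rng.uniform(1e-5, 0.04)) if is_deg else float(rng.uniform(0.06, 1.0))
        lfc = float(rng.normal(0, 0.3) + (rng.choice([-1.5, 1.5]) if is_deg else 0.0))
        deg_rows.append((g.name, lfc, p))
    degs = pd.DataFrame(deg_rows, columns=["gene", "log2fc", "p"])

    # --- signal track ----------------------------------------------------------
    from .intervals import merge as merge_ivs

    all_sorted = sorted(peak_ivs, key=lambda iv: (iv.chrom, iv.start))
    merged = merge_ivs(all_sorted)
    up_sorted = sorted((iv for iv, d in zip(peak_ivs, directions) if d == "up"),
                       key=lambda iv: (iv.chrom, iv.start))
    from .intervals import overlaps_any

    has_up = overlaps_any(merged, up_sorted)
    track = pd.DataFrame(
        [(m.chrom, m.start, m.end, 5.0 if u else 1.0)
         for m, u in zip(merged, has_up)],
        columns=["chrom", "start", "end", "value"])

    ctcf_up_b2 = sorted((te[i].interval for i in motif_elements
                         if te[i].te_subtype == cfg.target_subtype),
                        key=lambda iv: (iv.chrom, iv.start))

    realized = {
        "up_rate_target": float(np.mean([d == "up" for d, s in
                                         zip(directions, peak_src) if s is not None])),
        "up_rate_other": float(np.mean([d == "up" for d, s in
                                        zip(directions, peak_src) if s is None])),
        "configured_up_rate_target": cfg.up_rate_target,
        "motif_rate_target": len([i for i in motif_elements
                                  if te[i].te_subtype == cfg.target_subtype])
        / len(target_idx),
        "motif_rate_other_b2": (len([i for i in motif_elements
                                     if i in set(other_b2_idx)])
                                / len(other_b2_idx)),
        "convergent_frac": ko_loop_truth.count("convergent") / n_ko,
    }

    truth = TruthLabels(
        peak_direction=directions,
        peak_target_element=peak_src,
        motif_elements=motif_elements,
        ko_specific_loops=[(len(shared) + k, o) for k, o in enumerate(ko_loop_truth)],
        dmr_regions=dmr_truth,
        linked_genes=sorted(linked),
        deg_genes=sorted(set(linked) | set(map(str, other_degs))),
        realized=realized,
    )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return Bundle(cfg, genome, te, genes, atac_diff, cpg_records,
                  dict(cfg.samples), pwm, wt_loops, ko_loops, degs,
                  ctcf_up_b2, track, truth)


def simulate_oriented_loops(n_loops: int = 500, convergent_frac: float = 0.70,
                            divergent_frac: float = 0.10,
                            anchor_width: int = 1000, seed: int = 0):
    """A dedicated loop set with planted CTCF motif orientations.

    Anchors tile one toy chromosome; each anchor carries one planted motif
    instance whose strand realizes the loop's orientation; orientation
    counts are exact (``round(n * frac)``).  Returns
    (genome, loops, truth_orientations, pwm).
    """
    rng = np.random.default_rng(seed)
    pwm = default_ctcf_pwm()
    consensus = pwm.consensus
    from .motif import revcomp

    n_conv = int(round(n_loops * convergent_frac))
    n_div = int(round(n_loops * divergent_frac))
    orientations = (["convergent"] * n_conv + ["divergent"] * n_div
                    + ["tandem"] * (n_loops - n_conv - n_div))
    rng.shuffle(orientations)

    size = 2 * n_loops * anchor_width + 2000
    codes = rng.integers(0, 4, size=size)
    seq = bytearray(_BASES[codes].tobytes())
    loops, truth = [], []
    for k, orient in enumerate(orientations):
        if orient == "convergent":
            sl, sr = "+", "-"
        elif orient == "divergent":
            sl, sr = "-", "+"
        else:
            sl = sr = "+" if rng.random() < 0.5 else "-"
        aL = GenomicInterval("chrS", (2 * k) * anchor_width,
                             (2 * k + 1) * anchor_width)
        aR = GenomicInterval("chrS", (2 * k + 1) * anchor_width,
                             (2 * k + 2) * anchor_width)
        for anchor, strand in ((aL, sl), (aR, sr)):
            start = anchor.midpoint - len(consensus) // 2
            inst = consensus if strand == "+" else revcomp(consensus)
            seq[start:start + len(consensus)] = inst.encode()
        loops.append(Loop(aL, aR, "KO"))
        truth.append(orient)
    return {"chrS": bytes(seq).decode("ascii")}, loops, truth, pwm


def null_bundle_config(seed: int = 0) -> SyntheticConfig:
    """A config with planting disabled: no enrichment, no DMRs, no linkage."""
    cfg = SyntheticConfig(seed=seed)
    cfg.up_odds_ratio = 1.0
    cfg.n_dmr_hypo_b2 = 0
    cfg.n_dmr_hypo_other = 0
    cfg.n_dmr_hyper = 0
    cfg.n_linked_degs = 0
    return cfg


def write_bundle(bundle: Bundle, outdir) -> dict:
    """Write the bundle as the text formats genomic_io reads; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "fasta": "genome.fa", "te": "te.tsv", "genes": "genes.tsv",
        "atac_diff": "atac_diff.tsv", "cpg": "cpg.tsv", "groups": "groups.tsv",
        "pwm": "ctcf.jaspar", "wt_loops": "wt.bedpe", "ko_loops": "ko.bedpe",
        "degs": "degs.tsv", "ctcf_up_b2": "ctcf_up_b2.bed",
        "track": "atac.bedgraph", "truth": "truth.json",
    }.items()}
    genomic_io.write_fasta(paths["fasta"], bundle.genome)
    genomic_io.write_te_annotation(paths["te"], bundle.te)
    genomic_io.write_genes(paths["genes"], bundle.genes)
    with open(paths["atac_diff"], "wt", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tlog2fc\tfdr\n")
        for r in sorted(bundle.atac_diff,
                        key=lambda r: (r.interval.chrom, r.interval.start)):
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.log2fc:.6g}\t"
                     f"{r.fdr:.6g}\n")
    genomic_io.write_cpg_table(paths["cpg"], bundle.cpg)
    with open(paths["groups"], "wt", encoding="utf-8") as fh:
        fh.write("#sample\tgroup\n")
        for s in sorted(bundle.group_map):
            fh.write(f"{s}\t{bundle.group_map[s]}\n")
    genomic_io.write_pwm_jaspar(paths["pwm"], bundle.pwm, name="CTCF_synthetic")
    genomic_io.write_loops(paths["wt_loops"], bundle.wt_loops)
    genomic_io.write_loops(paths["ko_loops"], bundle.ko_loops)
    bundle.degs.to_csv(paths["degs"], sep="\t", index=False)
    genomic_io.write_regions(paths["ctcf_up_b2"], bundle.ctcf_up_b2)
    genomic_io.write_bedgraph(paths["track"], bundle.track)
    truth = {
        "peak_direction": bundle.truth.peak_direction,
        "dmr_regions": bundle.truth.dmr_regions,
        "linked_genes": bundle.truth.linked_genes,
        "deg_genes": bundle.truth.deg_genes,
        "ko_specific_loops": bundle.truth.ko_specific_loops,
        "realized": bundle.truth.realized,
    }
    with open(paths["truth"], "wt", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
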