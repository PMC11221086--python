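"""End-to-end orchestration: run every analysis stage on one input bundle.

Stages mirror the analysis arc: TE enrichment of differential peaks (up and
down, by count and cumulative length, at three hierarchy levels), genomic
annotation, DMR calling plus quadrant integration, motif enrichment, loop
anchor/loop classification with CTCF orientation and binned anchor
profiles, permutation tests, signal profiles and DEG-loop linkage.  Each
stage writes one TSV and contributes to a machine-readable summary JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from . import genomic_io
from .intervals import make_windows
from .loops import (
    anchor_bin_profile,
    classify_anchors,
    classify_loops,
    link_deg_loops,
    orient_loops,
)
from .methylation import call_dmrs, filter_cpgs, quadrant_integration
from .models import OverlapRule
from .motif import motif_enrichment, scan_best
from .permutation import perm_test
from .profiles import compute_matrix, mean_profile
from .te_enrichment import (
    LEVELS,
    enrich_annotation,
    enrich_te,
    enrichment_to_frame,
    promoter_of,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths plus every tunable threshold, with study defaults."""

    bundle_dir: str
    alpha: float = 0.05
    lfc: float = 0.585
    min_frac_query: float = 0.5
    min_frac_target: float = 0.5
    either_satisfies: bool = True
    promoter_halfwidth: int = 3000
    dmr_q_low: float = 0.01
    dmr_q_high: float = 0.99
    dmr_max_gap: int = 300
    dmr_min_cpg: int = 3
    dmr_min_abs_diff: float = 0.1
    motif_threshold_frac: float = 0.8
    motif_pseudocount: float = 0.01
    n_bins: int = 100
    perm_iters: int = 200
    perm_seed: int = 1
    deg_p: float = 0.05
    target_family: str = "B2"
    target_subtype: str = "B3"
    paths: dict = field(default_factory=dict)

    def path(self, key: str, default_name: str) -> Path:
        p = Path(self.paths.get(key, Path(self.bundle_dir) / default_name))
        if not p.exists():
            raise FileNotFoundError(f"configuration: input {key!r} not found at {p}")
        return p

    @property
    def rule(self) -> OverlapRule:
        return OverlapRule(self.min_frac_query, self.min_frac_target,
                           self.either_satisfies)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"stage {name}: {e}") from e
        return run
    return wrap


def _read_groups(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: v for k, v in asdict(config).items()
                                if k != "paths"}}

    # ----- inputs (checked before any computation) -------------------------
    p_te = config.path("te", "te.tsv")
    p_diff = config.path("atac_diff", "atac_diff.tsv")
    p_genes = config.path("genes", "genes.tsv")
    p_cpg = config.path("cpg", "cpg.tsv")
    p_groups = config.path("groups", "groups.tsv")
    p_fasta = config.path("fasta", "genome.fa")
    p_pwm = config.path("pwm", "ctcf.jaspar")
    p_wt = config.path("wt_loops", "wt.bedpe")
    p_ko = config.path("ko_loops", "ko.bedpe")
    p_degs = config.path("degs", "degs.tsv")
    p_b2up = config.path("ctcf_up_b2", "ctcf_up_b2.bed")
    p_track = config.path("track", "atac.bedgraph")

    te = genomic_io.read_te_annotation(p_te)
    diff = genomic_io.read_regions(p_diff, "diff_table", config.alpha, config.lfc)
    genes = genomic_io.read_genes(p_genes)
    groups = _read_groups(p_groups)
    cpg = genomic_io.read_cpg_table(p_cpg, groups)
    pwm = genomic_io.read_pwm_jaspar(p_pwm)
    wt_loops, _ = genomic_io.read_loops(p_wt, genotype="WT")
    ko_loops, _ = genomic_io.read_loops(p_ko, genotype="KO")
    degs = genomic_io.read_deg_table(p_degs)
    ctcf_up_b2 = genomic_io.read_regions(p_b2up, "bed")
    track = genomic_io.read_bedgraph(p_track)
    fasta = pyfaidx.Fasta(str(p_fasta))
    rule = config.rule
    b2_elements = [t for t in te if t.te_family == config.target_family]

    up = [r for r in diff if r.direction == "up"]
    down = [r for r in diff if r.direction == "down"]

    # ----- TE enrichment ----------------------------------------------------
    @_stage("te_enrichment")
    def st_enrich():
        results = []
        for direction, fg in (("up", up), ("down", down)):
            for level in LEVELS:
                for mode in ("count", "length"):
                    for r in enrich_te(fg, diff, te, rule, level, mode):
                        results.append((direction, r))
        frame = enrichment_to_frame([r for _, r in results])
        frame.insert(0, "direction", [d for d, _ in results])
        frame.to_csv(out / "te_enrichment.tsv", sep="\t", index=False)
        sub = frame[(frame.direction == "up") & (frame.level == "b2_subtype")
                    & (frame["mode"] == "count")]
        # two-sided p is direction-blind: break p ties by fold enrichment
        top = (sub.sort_values(["p_adj", "fold_enrichment"],
                               ascending=[True, False]).iloc[0]
               if len(sub) else None)
        summary["te_enrichment"] = {
            "n_up": len(up), "n_down": len(down), "n_rows": len(frame),
            "top_up_b2_subtype": None if top is None else str(top.category),
            "top_up_b2_subtype_fe": None if top is None
            else round(float(top.fold_enrichment), 6),
            "top_up_b2_subtype_padj": None if top is None else float(top.p_adj),
        }
    st_enrich()

    # ----- genomic annotation ----------------------------------------------
    @_stage("annotation")
    def st_annot():
        res = enrich_annotation(up, diff, genes, config.promoter_halfwidth)
        enrichment_to_frame(res).to_csv(out / "annotation_enrichment.tsv",
                                        sep="\t", index=False)
        summary["annotation"] = {r.category: round(r.fold_enrichment, 6)
                                 for r in res}
    st_annot()

    # ----- DMRs and quadrant integration -----------------------------------
    @_stage("dmr")
    def st_dmr():
        kept = filter_cpgs(cpg, groups)
        dmrs = call_dmrs(kept, groups, q_low=config.dmr_q_low,
                         q_high=config.dmr_q_high, max_gap=config.dmr_max_gap,
                         min_cpg=config.dmr_min_cpg,
                         min_abs_diff=config.dmr_min_abs_diff)
        from .methylation import dmrs_to_frame

        dmrs_to_frame(dmrs).to_csv(out / "dmrs.tsv", sep="\t", index=False)
        records, fisher = quadrant_integration(dmrs, diff, b2_elements, rule)
        rows = [(r.dmr.interval.chrom, r.dmr.interval.start, r.dmr.interval.end,
                 r.atac.interval.start, r.atac.interval.end, r.dmr.mean_diff,
                 r.atac.log2fc, r.quadrant, r.is_b2) for r in records]
        pd.DataFrame(rows, columns=["chrom", "dmr_start", "dmr_end", "atac_start",
                                    "atac_end", "mean_diff", "log2fc", "quadrant",
                                    "is_b2"]).to_csv(out / "quadrant.tsv",
                                                     sep="\t", index=False)
        summary["dmr"] = {
            "n_cpg_retained": len(kept),
            "n_dmr": len(dmrs),
            "n_hypo": sum(d.status == "hypo" for d in dmrs),
            "n_hyper": sum(d.status == "hyper" for d in dmrs),
            "n_quadrant_pairs": len(records),
            "q4_fisher": None if fisher is None else {
                k: (round(v, 6) if isinstance(v, float) else v)
                for k, v in fisher.items()},
        }
        return dmrs
    st_dmr()

    # ----- motif enrichment -------------------------------------------------
    @_stage("motif_enrichment")
    def st_motif():
        threshold = config.motif_threshold_frac * pwm.max_score(
            config.motif_pseudocount)
        fg = [t.interval for t in b2_elements
              if t.te_subtype == config.target_subtype]
        bg = [t.interval for t in b2_elements]
        res = motif_enrichment(fg, bg, fasta, pwm, threshold,
                               config.motif_pseudocount)
        summary["motif_enrichment"] = {
            k: (round(v, 6) if isinstance(v, float) else v)
            for k, v in res.items() if not k.endswith("hits")}
    st_motif()

    # ----- loops ------------------------------------------------------------
    @_stage("loops")
    def st_loops():
        threshold = config.motif_threshold_frac * pwm.max_score(
            config.motif_pseudocount)
        cls = classify_anchors(wt_loops, ko_loops)
        loop_classes = classify_loops(wt_loops, ko_loops, cls)
        anchor_rows = ([(a.chrom, a.start, a.end, "NLA") for a in cls.nla]
                       + [(a.chrom, a.start, a.end, "LLA") for a in cls.lla]
                       + [(a.chrom, a.start, a.end, "ULA") for a in cls.ula])
        pd.DataFrame(sorted(anchor_rows),
                     columns=["chrom", "start", "end", "class"]).to_csv(
            out / "anchors.tsv", sep="\t", index=False)

        ko_cls = [lc for lc in loop_classes if lc.loop.genotype == "KO"]
        hits = []
        for lc in ko_cls:
            hl = scan_best(pwm, str(fasta[lc.loop.anchorL.chrom]
                                    [lc.loop.anchorL.start:lc.loop.anchorL.end]),
                           config.motif_pseudocount, threshold)
            hr = scan_best(pwm, str(fasta[lc.loop.anchorR.chrom]
                                    [lc.loop.anchorR.start:lc.loop.anchorR.end]),
                           config.motif_pseudocount, threshold)
            hits.append((hl, hr))
        calls, summary_orient = orient_loops([lc.loop for lc in ko_cls], hits)
        rows = []
        for lc, call in zip(ko_cls, calls):
            lp = lc.loop
            rows.append((lp.anchorL.chrom, lp.anchorL.start, lp.anchorL.end,
                         lp.anchorR.start, lp.anchorR.end, lc.klass,
                         call.left_strand, call.right_strand, call.orientation))
        pd.DataFrame(rows, columns=["chrom", "startL", "endL", "startR", "endR",
                                    "class", "left_strand", "right_strand",
                                    "orientation"]).to_csv(
            out / "loops.tsv", sep="\t", index=False)

        new_calls = [c for lc, c in zip(ko_cls, calls) if lc.klass == "new"
                     and c.orientation != "unclassified"]
        n_new_cls = len(new_calls)
        profile = anchor_bin_profile(cls.nla, [r.interval for r in up],
                                     config.n_bins)
        np.savetxt(out / "nla_bin_profile.tsv", profile[None, :],
                   delimiter="\t", fmt="%.6g")
        summary["loops"] = {
            "n_nla": len(cls.nla), "n_lla": len(cls.lla), "n_ula": len(cls.ula),
            "anchor_jaccard": round(cls.jaccard, 6),
            "n_new": sum(lc.klass == "new" for lc in ko_cls),
            "n_unchanged": sum(lc.klass == "unchanged" for lc in ko_cls),
            "n_lost": sum(lc.klass == "lost" for lc in loop_classes),
            "orientation": {k: (round(v, 6) if isinstance(v, float) else v)
                            for k, v in summary_orient.items()},
            "new_convergent_frac": (
                round(sum(c.orientation == "convergent" for c in new_calls)
                      / n_new_cls, 6) if n_new_cls else None),
        }
        return cls, loop_classes
    cls, loop_classes = st_loops()

    # ----- permutation tests -------------------------------------------------
    @_stage("permutation")
    def st_perm():
        universe = sorted(cls.nla + cls.lla + cls.ula,
                          key=lambda iv: (iv.chrom, iv.start))
        res_nla = perm_test(cls.nla, universe, ctcf_up_b2,
                            statistic="num_overlaps", n_iter=config.perm_iters,
                            alternative="greater", seed=config.perm_seed)
        promoters = [promoter_of(g, config.promoter_halfwidth) for g in genes]
        name_to_prom = {p.name: p for p in promoters}
        deg_proms = [name_to_prom[str(r.gene)]
                     for r in degs.itertuples(index=False)
                     if float(r.p) < config.deg_p and str(r.gene) in name_to_prom]
        new_anchors = sorted(
            {a for lc in loop_classes if lc.klass == "new"
             for a in (lc.loop.anchorL, lc.loop.anchorR)},
            key=lambda iv: (iv.chrom, iv.start))
        res_deg = perm_test(deg_proms, promoters, new_anchors,
                            statistic="num_overlaps", n_iter=config.perm_iters,
                            alternative="greater", seed=config.perm_seed + 1)
        def fmt(r):
            return {"observed": r.observed, "null_mean": round(r.null_mean, 6),
                    "null_sd": round(r.null_sd, 6),
                    "z": None if np.isnan(r.z) else round(r.z, 6),
                    "p_empirical": round(r.p_empirical, 6)}
        summary["permutation"] = {
            "nla_vs_ctcf_up_b2": fmt(res_nla),
            "deg_promoters_vs_new_loop_anchors": fmt(res_deg),
        }
    st_perm()

    # ----- signal profiles ---------------------------------------------------
    @_stage("signal_profiles")
    def st_profiles():
        up_b2 = [t.interval for t in b2_elements
                 if t.te_subtype == config.target_subtype]
        chrom_sizes = {name: len(fasta[name]) for name in fasta.keys()}
        mat = compute_matrix(track, up_b2, flank_up=1000, flank_down=1000,
                             body_bins=20, bin_size=10, skip_zeros=False,
                             chrom_sizes=chrom_sizes)
        prof = mean_profile(mat)
        np.savetxt(out / "b2_signal_profile.tsv", prof[None, :],
                   delimiter="\t", fmt="%.6g")
        body = prof[mat.n_flank_bins_up:mat.n_flank_bins_up + mat.n_body_bins]
        flank = np.concatenate([prof[:mat.n_flank_bins_up],
                                prof[-mat.n_flank_bins_down:]])
        summary["signal_profiles"] = {
            "n_regions": len(mat.regions),
            "body_mean": round(float(body.mean()), 6),
            "flank_mean": round(float(flank.mean()), 6),
        }
    st_profiles()

    # ----- DEG-loop linkage ---------------------------------------------------
    @_stage("deg_linkage")
    def st_link():
        links = link_deg_loops(degs, genes, loop_classes, ctcf_up_b2,
                               config.promoter_halfwidth, config.deg_p)
        rows = [(g, lp.anchorL.chrom, lp.anchorL.start, lp.anchorR.end, side)
                for g, lp, side in links]
        pd.DataFrame(sorted(rows), columns=["gene", "chrom", "loop_start",
                                            "loop_end", "anchor_side"]).to_csv(
            out / "linked_genes.tsv", sep="\t", index=False)
        summary["deg_linkage"] = {
            "n_links": len(links),
            "genes": sorted({g for g, _, _ in links}),
        }
    st_link()

    with open(out / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
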