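# teloopkit

Transposable-element (TE) centric integration of differential epigenomic
peaks, DNA methylation, CTCF motifs and chromatin loops.

## The problem

Loss of repressive chromatin regulators can de-repress specific TE families.
In the rodent genome the SINE **B2** family is of particular interest because
many B2 copies carry CTCF binding sites, so de-repressed B2 elements can gain
CTCF binding and rewire chromatin loops — with downstream effects on gene
expression. Testing that chain of events requires a series of
interval-statistics steps that are usually scattered across shell tools and
R packages:

- assigning differential ATAC/ChIP peaks to the TE hierarchy
  (class → SINE family → B2 subtype) with **reciprocal-fraction overlap**
  semantics (an overlap counts when it covers ≥ 50% of the peak *or* of the
  element);
- **enrichment** of a differential peak set against the all-peaks background,
  both by element count and by cumulative bp, with Fisher's exact test and
  Benjamini–Hochberg adjustment per hierarchy level;
- **DMR calling** from per-CpG counts: the per-CpG statistic
  `d_i = p̂_KO − p̂_WT` (pooled proportions), candidate CpGs in the empirical
  quantile tails (0.01, 0.99), same-sign grouping with `maxGap = 300` bp,
  and the filters ≥ 3 CpGs, |mean d| ≥ 0.1, autosomes only;
- **quadrant integration** of methylation difference against accessibility
  fold-change (the fourth quadrant is hypomethylated + more accessible);
- log-odds **PWM scanning** with best-hit (max-score) reporting and
  strand-aware CTCF motif **orientation** at loop anchor pairs
  (convergent `><`, divergent `<>`, tandem `>>`/`<<`);
- genotype comparison of merged **loop anchors** (new / lost / unchanged,
  NLA / LLA / ULA) and loop classification from the anchor classes;
- **resampling permutation tests** (`n_iter = 200` draws of |query| regions
  from a universe without replacement) with overlap-count or mean-distance
  statistics and +1-smoothed empirical p.

`teloopkit` implements the whole arc as one tested Python package, plus a
synthetic-data generator that plants every signal with known ground truth so
each stage can be validated end to end.

## Worked example

```python
from teloopkit.synthetic import SyntheticConfig, generate
from teloopkit.te_enrichment import enrich_te
from teloopkit.methylation import filter_cpgs, call_dmrs
from teloopkit.loops import classify_anchors
from teloopkit.models import OverlapRule

bundle = generate(SyntheticConfig(seed=42))   # toy genome + truth labels
up = [r for r in bundle.atac_diff if r.direction == "up"]
rule = OverlapRule(0.5, 0.5, either_satisfies=True)
for r in sorted(enrich_te(up, bundle.atac_diff, bundle.te, rule,
                          level="b2_subtype", mode="count"),
                key=lambda r: (r.p_adj, -r.fold_enrichment)):
    print(f"{r.category:8s} FE={r.fold_enrichment:5.2f}  p_adj={r.p_adj:.2e}")

dmrs = call_dmrs(filter_cpgs(bundle.cpg, bundle.group_map), bundle.group_map)
print(f"{len(dmrs)} DMRs ({sum(d.status == 'hypo' for d in dmrs)} hypo)")

cls = classify_anchors(bundle.wt_loops, bundle.ko_loops)
print(f"NLA={len(cls.nla)} LLA={len(cls.lla)} ULA={len(cls.ula)} "
      f"Jaccard={cls.jaccard:.3f}")
```

prints

```
B3       FE= 2.74  p_adj=5.79e-09
B2_Mm2   FE= 0.62  p_adj=2.30e-01
B3A      FE= 1.13  p_adj=6.18e-01
B2_Mm1t  FE= 0.69  p_adj=6.18e-01
B2_Mm1a  FE= 0.96  p_adj=1.00e+00
58 DMRs (47 hypo)
NLA=160 LLA=160 ULA=340 Jaccard=0.515
```

The generator planted up-regulated peaks on the B3 subtype at an odds ratio
of 5, and B3 is recovered as the only significantly enriched subtype
(fold enrichment 2.74). The 58 called DMRs correspond to the planted
hypo/hyper-methylated regions (recall and precision against the truth
labels are computed by the test suite and `scripts/acceptance.py`); the
loop-anchor comparison finds the 160 knockout-specific anchors that were
placed on motif-bearing B3 elements.

## Command line

Every stage is also a subcommand: `teloopkit simulate`, `enrich`,
`annotate`, `dmr`, `motif-scan`, `permtest`, `run-all`.

```sh
teloopkit simulate --seed 42 --out bundle/
teloopkit run-all --bundle bundle/ --out results/
```

`run-all` writes one TSV per stage and a machine-readable `summary.json`,
and is byte-for-byte reproducible given the same seeds.

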