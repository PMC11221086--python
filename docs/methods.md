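# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical conventions that matter when comparing results.

## Coordinates and overlap semantics

All coordinates are 0-based half-open. Abutting intervals
(`[0,10)`, `[10,20)`) neither overlap nor merge; this keeps interval
arithmetic consistent (`covered bp = Σ(end − start)` after merging).
RepeatMasker `.out` rows (1-based begin) are converted at the I/O boundary.

Peak-to-TE assignment uses reciprocal-fraction overlap: a (peak, element)
pair qualifies when the overlap covers at least `min_frac_query` of the
peak **and/or** `min_frac_target` of the element. The defaults are
0.5 / 0.5 with the either/OR combination — the bedtools `-f 0.5 -F 0.5 -e`
convention. Fraction thresholds are inclusive (≥). A peak overlapping
several elements of one category counts once for that category; overlapping
elements of different categories counts once per category.

## Enrichment statistics

For each category of a hierarchy level (TE class; SINE family restricted to
`te_class == SINE`; B2 subtype restricted to `te_family == B2`) a 2×2 table
is built from a foreground region set and a background set that must
contain it (all detected peaks serve as the background for differential
peaks; all B2 elements for B2-restricted questions).

- **Count mode** cells: regions hitting ≥ 1 element of the category vs not,
  foreground vs background. This is the primary statistical readout.
- **Length mode** cells: cumulative bp of the *distinct* elements of the
  category hit by the region set, against the bp of the hit elements of the
  level's other categories (the level-complement). Base pairs are not
  independent trials, so the Fisher p in this mode is nominal only —
  with bp-scale counts it routinely underflows to 0 for enriched *and*
  depleted categories alike. Fold enrichment is the primary length-mode
  readout, and any "top category" ranking orders by
  (adjusted p ascending, fold enrichment descending), because the
  two-sided p is direction-blind.

Fisher's test is the two-sided conditional exact test (sum of
hypergeometric probabilities not exceeding the observed table's);
adjustment is Benjamini–Hochberg step-up across the categories of one
level and one direction. Fold enrichment is the ratio of in-category
frequencies (foreground over background); a 0/0 frequency ratio is
reported as NaN rather than invented.

Genomic annotation uses strand-aware TSS (interval start on `+`, end on
`-`), promoter = TSS ± 3000 bp (half-open), and the precedence
promoter > gene body > intergenic.

## DMR calling

CpGs are first filtered: retained when covered by ≥ 2 reads in ≥ 1 sample
of *each* group. The per-CpG statistic is the pooled-proportion difference

    d_i = (Σ KO methylated / Σ KO total) − (Σ WT methylated / Σ WT total).

Candidate CpGs fall below the 0.01 or above the 0.99 empirical quantile of
all d_i; same-sign candidates with successive gaps ≤ 300 bp form candidate
regions; a region is a DMR when it has ≥ 3 CpGs, |mean d_i| ≥ 0.1 and lies
on an autosome (everything except chrX/chrY/chrM by default). The DMR
interval spans the first to last candidate CpG (+1 bp, half-open).

This deliberately replaces a kernel-smoothed t-statistic (the bsseq/BSmooth
approach) with the raw pooled difference: the *selection and filtering
logic* (quantile cutoffs, maxGap grouping, CpG-count/effect/chromosome
filters) is identical, but no equivalence of the per-CpG statistic itself
is claimed. Consequences worth knowing:

- the quantile cutoff adapts to the data: the lower tail is a mixture of
  planted/real signal and binomial noise, so per-CpG capture probability
  depends on the signal fraction among all CpGs;
- with pooled coverage T per group the null standard deviation of d_i is
  ≈ √(2·p(1−p)/T); at coverage 10 × 2 replicates and p ≈ 0.85 this is
  ≈ 0.11, so a Δ = 0.3 region needs several CpGs for reliable capture —
  hence the ≥ 3 CpG filter does real work.

Quadrant integration pairs significant DMRs with significant differential
peaks by ≥ 1 bp overlap; the quadrant is the sign pair
(accessibility log2FC, methylation difference) with Q4 = (+, −), i.e.
hypomethylated and more accessible. `is_b2` marks pairs where either member
overlaps a B2 element under the reciprocal rule; a Fisher test on
{B2, non-B2} × {Q4, not-Q4} quantifies whether B2-linked pairs concentrate
in the fourth quadrant. The reported fold enrichment is the Q4 rate among
B2 pairs over the overall Q4 rate.

## Motif scanning and orientation

PWM columns receive a pseudocount (default 0.01 per cell, renormalized);
scores are Σ log2(p/bg) over the motif window with a uniform background by
default. The minus strand scores the reverse complement; windows containing
N are skipped; ties break to the smaller offset, then the plus strand. Only
the best hit per region is kept (max-score convention). Because a best hit
always exists, a pass threshold is needed for enrichment and orientation
calls: the default is 80% of the PWM's maximum attainable score, exposed as
a parameter.

Loop orientation reads the strands of the best passing hits at the two
anchors: (+,−) convergent, (−,+) divergent, equal strands tandem; loops
with a failing anchor are reported unclassified rather than guessed.
Orientation fractions are reported over classified loops.

## Loop anchors and classes

Both ends of every loop are pooled per genotype and merged. A merged KO
anchor overlapping (≥ 1 bp) any merged WT anchor is *shared*, otherwise a
new loop anchor (NLA); symmetrically lost (LLA) for WT; the merged union of
all shared anchors forms the unchanged set (ULA). The element-mode Jaccard
is |ULA| / (|NLA| + |LLA| + |ULA|). A KO loop is *new* when ≥ 1 anchor
overlaps an NLA component, else *unchanged*; a WT loop is *lost* when ≥ 1
anchor overlaps an LLA component (WT loops whose anchors all persist are
the unchanged KO loops' counterparts and are not emitted separately).
The ≥ 1 bp matching rule on merged anchors is the simplest auditable
convention; published Venn counts from other matching conventions need not
reproduce under it.

Anchor profiles split each anchor into `n` equal-as-possible windows
(winnum convention: the first `len mod n` windows get the extra bp) and
count overlapping peaks per window, averaged over anchors.

## Permutation tests

`perm_test` redraws |query| regions from a universe uniformly without
replacement each iteration (the regioneR `resampleRegions` scheme;
default 200 iterations) and recomputes the statistic: `num_overlaps`
(regions overlapping ≥ 1 feature) or `mean_distance` (mean midpoint
distance to the nearest feature). The empirical p is
`(1 + #as-or-more-extreme) / (n_iter + 1)` — never exactly zero — and a
z-score against the null mean/sd is reported alongside, plus the
observed/expected ratio, so either effect-size convention can be read off.
Note that `num_overlaps` on a small universe is hypergeometric-discrete:
its p-values are lumpy and calibration statements (uniformity of p under
the null) only hold for effectively continuous statistics such as
`mean_distance`.

## The synthetic generator

`synthetic.generate` builds a self-consistent bundle from one seeded
generator (no global random state); identical config + seed reproduce every
file byte for byte.

Defaults and what they emulate:

- **Genome**: 2 chromosomes × 5 Mb of i.i.d. uniform bases — this keeps the
  PWM null distribution analytically predictable. Planted motif instances
  are the only non-random sequence.
- **TEs**: 4000 non-overlapping elements; class mix
  SINE 0.55 / LINE 0.20 / LTR 0.15 / DNA 0.10; SINE families
  B2 0.50 / Alu 0.30 / MIR 0.20; B2 subtypes B3 0.35 / B3A 0.25 /
  B2_Mm2 0.20 / B2_Mm1t 0.10 / B2_Mm1a 0.10. Lengths: SINE U(120, 220) bp,
  LINE U(500, 4000), LTR U(300, 3000), DNA U(200, 1000).
- **Differential peaks** (1500): 150 on the target subtype (B3), 600 on
  other B2, 300 on non-B2 TEs, 450 background. Up-direction planted at an
  odds ratio of 5 on the target (baseline up-rate 0.08 elsewhere →
  up-rate ≈ 0.30 on target), with exact counts so realized rates are within
  ±2% of configured; 10% of the remainder are down, the rest ns. The
  placement split keeps the target's share of B2-hit bp low enough in the
  background that cumulative-length enrichment is informative, not
  saturated.
- **Motifs**: a near-one-hot 12-bp CTCF-like PWM around a deliberately
  non-palindromic consensus (so a planted instance's strand is
  unambiguous); planted in 60% of target-subtype elements and 10% of other
  B2 elements.
- **Methylation**: 75 000 background CpGs with shared WT/KO per-CpG truth
  from a Beta(34, 6) (90%) or Beta(6, 34) (10%, island-like) distribution;
  read counts Binomial(10, p) per sample, 2 samples per group. Planted
  DMRs: 40 hypomethylated (Δ = −0.3) on up-peak B3 elements, 10 on other up
  peaks, 10 hypermethylated (Δ = +0.3, low-methylation baseline), each with
  12–18 CpGs spaced 30–60 bp. These densities follow from the tail-capture
  arithmetic above: they make per-CpG capture ≈ 0.5 at the 1% quantile
  cutoff while keeping the planted fraction of CpGs near 1%, so ≥ 3-CpG
  recovery per region is reliable and background candidates almost never
  cluster within 300 bp.
- **Loops**: 5-kb anchors; 170 shared loops, 80 WT-specific, 80
  KO-specific. KO-specific anchors are centered on motif-bearing B3
  elements with orientations drawn as exact counts from
  convergent 0.70 / divergent 0.10 / tandem 0.20.
  `simulate_oriented_loops` is a dedicated variant (default n = 500, 1-kb
  anchors on a tiling chromosome) for orientation studies at larger n.
- **Expression**: 200 genes; 12 DEGs whose TSS sit inside KO-specific loop
  anchors (the planted linkage truth) plus 20 DEGs placed ≥ 20 kb from any
  KO-specific anchor; non-DEG p-values ≥ 0.06.
- **Signal track**: value 5.0 over merged peak regions containing an up
  peak, 1.0 over other peaks, 0 elsewhere (bedGraph sparsity).

What it does **not** emulate: real nucleotide composition and repeat
sequence divergence, correlated replicate structure, smoothly varying
methylation, contact-matrix noise (loop lists are consumed as given),
multi-part RepeatMasker elements (each row is an independent element) and
overlapping TE nesting. Passing recovery tests therefore demonstrates that
the *analysis logic* is correct under controlled conditions, not that the
pipeline's statistical power matches real data.

## Problem sizes and numerics

The test suite and the acceptance script run the bundle at the default
sizes above (about 4–5 s to generate, about 2 s for the full pipeline).
Oracle-equivalence checks use ≥ 200 randomized instances per primitive with
exact agreement; Fisher p-values are compared with an independent
`math.comb` enumeration at 1e-12. Permutation calibration uses 500
replicates of a null query at 200 iterations with the mean-distance
statistic. Floating-point determinism is maintained by sorting every
collection before iteration and deriving all randomness from the one seeded
generator; `summary.json` is byte-identical across reruns with equal seeds.

## Known limitations

- Length-mode Fisher p-values are nominal (see above); only fold
  enrichment should be interpreted.
- The DMR stand-in statistic ignores replicate-level variance; a region
  driven by one aberrant replicate can pass pooling when a smoothed
  t-statistic would not.
- Anchor matching by ≥ 1 bp on merged anchors makes NLA/LLA/ULA counts
  sensitive to anchor width; comparisons should keep the loop-calling
  resolution fixed across genotypes.
- `num_overlaps` permutation p-values are discrete; use `mean_distance`
  when p-value calibration matters.
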