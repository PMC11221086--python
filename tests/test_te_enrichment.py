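"""Fisher/BH statistics against enumeration oracles; TE and annotation
enrichment on constructed and planted inputs."""

from math import comb

import numpy as np
import pytest

from teloopkit.models import DifferentialRegion, GenomicInterval, OverlapRule, TEElement
from teloopkit.te_enrichment import (
    annotate_regions,
    bh_adjust,
    enrich_annotation,
    enrich_te,
    fisher_test,
    promoter_of,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Independent of scipy: sums P(table) over the support for tables whose
    probability does not exceed the observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1)
               if pmf(x) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_proportional_table(self):
        odds, p = fisher_test(5, 5, 5, 5)
        assert odds == 1.0 and p == 1.0

    def test_diagonal_table_hand_enumeration(self):
        # support {0,1,2}: P(2)=P(0)=1/6, P(1)=4/6; two-sided p = 2/6
        _, p = fisher_test(2, 0, 0, 2)
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b == 0) or (c + d == 0) or (a + b + c + d == 0):
                continue
            _, p = fisher_test(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(fisher_oracle(int(a), int(b), int(c), int(d)),
                                      abs=1e-12)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert fisher_test(a, b, c, d)[1] == pytest.approx(
                fisher_test(a, c, b, d)[1], abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_test(0, 0, 0, 0)


class TestBH:
    def test_hand_step_up(self):
        # p_(i) * m / i = .04, .04, .04, .04 after monotonicity
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_stay_equal(self):
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=30)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


def _diff(chrom, start, end, direction="up"):
    lfc = 1.0 if direction == "up" else (-1.0 if direction == "down" else 0.0)
    fdr = 0.01 if direction != "ns" else 0.5
    return DifferentialRegion(GenomicInterval(chrom, start, end), lfc, fdr,
                              direction)


def _te(chrom, start, end, sub):
    return TEElement(GenomicInterval(chrom, start, end), "SINE", "B2", sub)


RULE = OverlapRule(0.5, 0.5, True)


class TestEnrichTE:
    def test_foreground_equals_background_is_flat(self):
        te = [_te("chr1", 100, 300, "B3"), _te("chr1", 1000, 1200, "B3A")]
        regions = [_diff("chr1", 90, 310), _diff("chr1", 990, 1210),
                   _diff("chr1", 5000, 5100)]
        for r in enrich_te(regions, regions, te, RULE, "b2_subtype", "count"):
            assert r.fold_enrichment == pytest.approx(1.0)
            assert r.p == pytest.approx(1.0)

    def test_equal_length_elements_make_modes_agree(self):
        # all elements 200 bp: length-mode cells are 200x the element counts,
        # so fold enrichment matches an element-count computation
        te = [_te("chr1", i * 1000, i * 1000 + 200, "B3" if i % 2 else "B3A")
              for i in range(10)]
        bg = [_diff("chr1", i * 1000, i * 1000 + 200) for i in range(10)]
        fg = bg[:4]
        count_on_elements = {}
        for r in enrich_te(fg, bg, te, RULE, "b2_subtype", "length"):
            a, b = r.observed_in // 200, r.observed_out // 200
            c, d = r.background_in // 200, r.background_out // 200
            count_on_elements[r.category] = ((a / (a + b)) / (c / (c + d)))
            assert r.fold_enrichment == pytest.approx(count_on_elements[r.category])

    def test_planted_subtype_is_unique_minimum(self, bundle):
        up = [r for r in bundle.atac_diff if r.direction == "up"]
        res = enrich_te(up, bundle.atac_diff, bundle.te, RULE,
                        "b2_subtype", "count")
        best = min(res, key=lambda r: r.p_adj)
        assert best.category == bundle.config.target_subtype
        assert best.fold_enrichment > 1

    def test_foreground_outside_background_rejected(self):
        te = [_te("chr1", 100, 300, "B3")]
        bg = [_diff("chr1", 0, 50)]
        fg = [_diff("chr1", 90, 310)]
        with pytest.raises(ValueError, match="background"):
            enrich_te(fg, bg, te, RULE, "b2_subtype", "count")


class TestAnnotate:
    GENE_PLUS = GenomicInterval("chr1", 10_000, 20_000, "+", "gA")
    GENE_MINUS = GenomicInterval("chr1", 10_000, 20_000, "-", "gB")

    def test_promoter_window_on_plus_strand(self):
        peak = GenomicInterval("chr1", 7_500, 8_000)
        assert annotate_regions([peak], [self.GENE_PLUS]) == ["promoter"]

    def test_gene_body(self):
        peak = GenomicInterval("chr1", 15_000, 15_500)
        assert annotate_regions([peak], [self.GENE_PLUS]) == ["gene_body"]

    def test_minus_strand_tss_at_gene_end(self):
        peak = GenomicInterval("chr1", 22_500, 22_900)
        assert annotate_regions([peak], [self.GENE_MINUS]) == ["promoter"]
        assert annotate_regions([peak], [self.GENE_PLUS]) == ["intergenic"]

    def test_promoter_takes_precedence_over_body(self):
        peak = GenomicInterval("chr1", 11_000, 11_500)  # inside gene and window
        assert annotate_regions([peak], [self.GENE_PLUS]) == ["promoter"]

    def test_unstranded_gene_rejected(self):
        gene = GenomicInterval("chr1", 0, 100, ".")
        with pytest.raises(ValueError):
            promoter_of(gene)


class TestEnrichAnnotation:
    def test_direct_ratio(self):
        # fg: the single promoter region; bg: half promoters -> FE = 2
        gene = GenomicInterval("chr1", 100_000, 110_000, "+", "g")
        prom_peak = GenomicInterval("chr1", 98_000, 98_500)
        far = [GenomicInterval("chr1", 500_000 + i * 10_000, 500_400 + i * 10_000)
               for i in range(1)]
        bg = [prom_peak] + far
        res = enrich_annotation([prom_peak], bg, [gene])
        by_cat = {r.category: r for r in res}
        assert by_cat["promoter"].fold_enrichment == pytest.approx(2.0)

    def test_flat_when_equal(self):
        gene = GenomicInterval("chr1", 100_000, 110_000, "+", "g")
        bg = [GenomicInterval("chr1", 98_000, 98_500),
              GenomicInterval("chr1", 500_000, 500_400)]
        for r in enrich_annotation(bg, bg, [gene]):
            if r.observed_in:
                assert r.fold_enrichment == pytest.approx(1.0)
            assert r.p == pytest.approx(1.0)

    def test_bundle_annotation_enrichment_well_formed(self, bundle):
        up = [r for r in bundle.atac_diff if r.direction == "up"]
        res = enrich_annotation(up, bundle.atac_diff, bundle.genes)
        assert {r.category for r in res} == {"promoter", "gene_body", "intergenic"}
        for r in res:
            assert r.p_adj >= r.p - 1e-12
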