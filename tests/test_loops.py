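"""Anchor/loop classification, motif orientation, bin profiles, DEG linkage."""

import numpy as np
import pandas as pd
import pytest

from teloopkit.intervals import make_windows
from teloopkit.loops import (
    anchor_bin_profile,
    classify_anchors,
    classify_loops,
    link_deg_loops,
    LoopClass,
    orient_loops,
    orientation_of,
)
from teloopkit.models import GenomicInterval, Loop, MotifHit


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def loop(s1, e1, s2, e2, genotype="KO", chrom="chr1"):
    return Loop(iv(s1, e1, chrom), iv(s2, e2, chrom), genotype)


class TestClassifyAnchors:
    def test_hand_enumerated_three_anchor_case(self):
        wt = [loop(0, 10_000, 20_000, 30_000, "WT")]
        ko = [loop(0, 10_000, 40_000, 50_000, "KO")]
        cls = classify_anchors(wt, ko)
        assert (len(cls.nla), len(cls.lla), len(cls.ula)) == (1, 1, 1)
        assert cls.jaccard == pytest.approx(1 / 3)
        assert cls.nla == [iv(40_000, 50_000)]
        assert cls.lla == [iv(20_000, 30_000)]

    def test_identical_loop_lists(self):
        wt = [loop(0, 5_000, 50_000, 55_000, "WT")]
        ko = [loop(0, 5_000, 50_000, 55_000, "KO")]
        cls = classify_anchors(wt, ko)
        assert len(cls.nla) == len(cls.lla) == 0
        assert cls.jaccard == 1.0

    def test_fully_disjoint_anchors(self):
        wt = [loop(0, 5_000, 50_000, 55_000, "WT")]
        ko = [loop(10_000, 15_000, 70_000, 75_000, "KO")]
        cls = classify_anchors(wt, ko)
        assert len(cls.ula) == 0 and cls.jaccard == 0.0

    def test_genotype_swap_symmetry(self, bundle):
        fwd = classify_anchors(bundle.wt_loops, bundle.ko_loops)
        rev = classify_anchors(bundle.ko_loops, bundle.wt_loops)
        assert fwd.nla == rev.lla and fwd.lla == rev.nla
        assert fwd.ula == rev.ula
        assert fwd.jaccard == pytest.approx(rev.jaccard)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            classify_anchors([], [loop(0, 10, 50, 60)])


class TestClassifyLoops:
    def test_partition_of_ko_loops(self, bundle):
        cls = classify_anchors(bundle.wt_loops, bundle.ko_loops)
        out = classify_loops(bundle.wt_loops, bundle.ko_loops, cls)
        ko = [x for x in out if x.loop.genotype == "KO"]
        assert len(ko) == len(bundle.ko_loops)
        n_new = sum(x.klass == "new" for x in ko)
        n_unchanged = sum(x.klass == "unchanged" for x in ko)
        assert n_new + n_unchanged == len(bundle.ko_loops)
        assert {x.klass for x in out} <= {"new", "unchanged", "lost"}

    def test_planted_new_loops_recovered(self, bundle):
        cls = classify_anchors(bundle.wt_loops, bundle.ko_loops)
        out = classify_loops(bundle.wt_loops, bundle.ko_loops, cls)
        ko = [x for x in out if x.loop.genotype == "KO"]
        new_idx = {i for i, x in enumerate(ko) if x.klass == "new"}
        planted = {i for i, _ in bundle.truth.ko_specific_loops}
        assert new_idx == planted

    def test_constructed_cases(self):
        wt = [loop(0, 5_000, 50_000, 55_000, "WT"),
              loop(100_000, 105_000, 200_000, 205_000, "WT")]
        ko = [loop(0, 5_000, 50_000, 55_000, "KO"),
              loop(0, 5_000, 300_000, 305_000, "KO")]
        cls = classify_anchors(wt, ko)
        out = {(x.loop.anchorR.start, x.loop.genotype): x.klass
               for x in classify_loops(wt, ko, cls)}
        assert out[(50_000, "KO")] == "unchanged"
        assert out[(300_000, "KO")] == "new"
        assert out[(200_000, "WT")] == "lost"


class TestOrientation:
    @pytest.mark.parametrize("left,right,expected", [
        ("+", "-", "convergent"), ("-", "+", "divergent"),
        ("+", "+", "tandem"), ("-", "-", "tandem"),
        ("none", "+", "unclassified"), ("+", "none", "unclassified"),
        ("none", "none", "unclassified")])
    def test_truth_table(self, left, right, expected):
        assert orientation_of(left, right) == expected

    def test_fractions_sum_to_one_over_classified(self):
        loops = [loop(i * 100_000, i * 100_000 + 5000,
                      i * 100_000 + 50_000, i * 100_000 + 55_000)
                 for i in range(4)]
        def hit(strand, passes=True):
            return MotifHit(0, 10.0, strand, 0, passes)
        hits = [(hit("+"), hit("-")), (hit("-"), hit("+")),
                (hit("+"), hit("+")), (hit("+"), hit("-", passes=False))]
        calls, summary = orient_loops(loops, hits)
        assert summary["n_classified"] == 3 and summary["n_unclassified"] == 1
        total = sum(summary[o] for o in ("convergent", "divergent", "tandem"))
        assert total == pytest.approx(1.0)


class TestAnchorBinProfile:
    def test_full_cover_peak(self):
        anchors = [iv(0, 1000)]
        assert np.array_equal(anchor_bin_profile(anchors, [iv(0, 1000)], 100),
                              np.ones(100))

    def test_no_peaks(self):
        assert np.array_equal(anchor_bin_profile([iv(0, 1000)], [], 100),
                              np.zeros(100))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        anchors = [iv(int(s), int(s) + 2000)
                   for s in sorted(rng.integers(0, 80_000, size=10) * 1)]
        peaks = sorted((iv(int(s), int(s) + int(rng.integers(50, 500)))
                        for s in rng.integers(0, 90_000, size=60)),
                       key=lambda x: x.start)
        got = anchor_bin_profile(anchors, peaks, 20)
        rows = []
        for a in anchors:
            counts = []
            for b in make_windows(a, 20):
                counts.append(sum(b.overlap_bp(p) > 0 for p in peaks))
            rows.append(counts)
        assert np.allclose(got, np.mean(rows, axis=0))

    def test_additivity_over_disjoint_peak_sets(self):
        rng = np.random.default_rng(6)
        anchors = [iv(0, 2000), iv(10_000, 12_000)]
        set_a = [iv(100, 300), iv(10_500, 10_700)]
        set_b = [iv(1500, 1900), iv(11_000, 11_800)]
        both = sorted(set_a + set_b, key=lambda x: x.start)
        assert np.allclose(
            anchor_bin_profile(anchors, both, 10),
            anchor_bin_profile(anchors, set_a, 10)
            + anchor_bin_profile(anchors, set_b, 10))

    def test_short_anchor_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = anchor_bin_profile([iv(0, 5), iv(100, 1100)], [iv(0, 2000)], 10)
        assert np.array_equal(out, np.ones(10))


class TestDegLinkage:
    def _setup(self):
        lp = loop(100_000, 105_000, 500_000, 505_000, "KO")
        b2 = [iv(502_000, 502_200)]          # on the right anchor
        gene = GenomicInterval("chr1", 103_000, 113_000, "+", "gX")
        degs = pd.DataFrame({"gene": ["gX"], "log2fc": [1.2], "p": [0.001]})
        return lp, b2, [gene], degs

    def test_deg_on_b2_anchored_new_loop_reported(self):
        lp, b2, genes, degs = self._setup()
        links = link_deg_loops(degs, genes, [LoopClass(lp, "new")], b2)
        assert [(g, side) for g, _, side in links] == [("gX", "left")]

    def test_unchanged_loop_not_reported(self):
        lp, b2, genes, degs = self._setup()
        assert link_deg_loops(degs, genes, [LoopClass(lp, "unchanged")], b2) == []

    def test_non_significant_gene_not_reported(self):
        lp, b2, genes, degs = self._setup()
        degs.loc[0, "p"] = 0.2
        assert link_deg_loops(degs, genes, [LoopClass(lp, "new")], b2) == []

    def test_missing_gene_model_warns(self):
        lp, b2, genes, degs = self._setup()
        degs = pd.concat([degs, pd.DataFrame(
            {"gene": ["absent"], "log2fc": [1.0], "p": [0.01]})])
        with pytest.warns(UserWarning, match="absent from the gene model"):
            links = link_deg_loops(degs, genes, [LoopClass(lp, "new")], b2)
        assert len(links) == 1

    def test_bundle_truth_wiring_recovered(self, bundle):
        cls = classify_anchors(bundle.wt_loops, bundle.ko_loops)
        out = classify_loops(bundle.wt_loops, bundle.ko_loops, cls)
        links = link_deg_loops(bundle.degs, bundle.genes, out,
                               bundle.ctcf_up_b2)
        assert sorted({g for g, _, _ in links}) == bundle.truth.linked_genes
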