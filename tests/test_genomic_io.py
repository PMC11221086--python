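"""Format readers/writers: coordinate conventions, validation, round-trips."""

import numpy as np
import pytest

from teloopkit import genomic_io
from teloopkit.genomic_io import ParseError, SchemaError
from teloopkit.models import CpGRecord, GenomicInterval, Loop


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadRegions:
    def test_bed6_field_mapping(self, tmp_path):
        p = write(tmp_path, "a.bed", "chr1\t0\t100\tpk1\t0\t+\n")
        (iv,) = genomic_io.read_regions(p, "bed")
        assert (iv.chrom, iv.start, iv.end, iv.strand, iv.name) == \
            ("chr1", 0, 100, "+", "pk1")

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = write(tmp_path, "a.bed",
                  "track name=x\n# comment\nbrowser position\nchr1\t5\t10\n")
        assert len(genomic_io.read_regions(p, "bed")) == 1

    def test_invalid_coordinates_name_the_line(self, tmp_path):
        p = write(tmp_path, "a.bed", "chr1\t0\t10\nchr1\t50\t40\n")
        with pytest.raises(ParseError, match="a.bed:2"):
            genomic_io.read_regions(p, "bed")

    @pytest.mark.parametrize("log2fc,fdr,expected", [
        (1.0, 0.01, "up"),        # passes both thresholds
        (0.5, 0.01, "ns"),        # |lfc| below 0.585
        (-1.0, 0.01, "down"),
        (1.0, 0.05, "ns"),        # FDR not strictly below alpha
        (0.585, 0.049, "up"),     # lfc threshold is inclusive
    ])
    def test_diff_table_direction_thresholds(self, tmp_path, log2fc, fdr, expected):
        p = write(tmp_path, "d.tsv",
                  f"chrom\tstart\tend\tlog2fc\tfdr\nchr1\t0\t100\t{log2fc}\t{fdr}\n")
        (r,) = genomic_io.read_regions(p, "diff_table")
        assert r.direction == expected

    def test_diff_table_missing_column(self, tmp_path):
        p = write(tmp_path, "d.tsv", "chrom\tstart\tend\tlog2fc\nchr1\t0\t9\t1\n")
        with pytest.raises(SchemaError, match="fdr"):
            genomic_io.read_regions(p, "diff_table")

    def test_output_sorted(self, tmp_path):
        p = write(tmp_path, "a.bed", "chr2\t5\t10\nchr1\t50\t60\nchr1\t5\t10\n")
        ivs = genomic_io.read_regions(p, "bed")
        assert [(i.chrom, i.start) for i in ivs] == \
            [("chr1", 5), ("chr1", 50), ("chr2", 5)]


class TestTEAnnotation:
    def test_te_bed_hierarchy(self, tmp_path):
        p = write(tmp_path, "te.tsv", "chr1\t500\t680\tSINE\tB2\tB3A\n")
        (t,) = genomic_io.read_te_annotation(p)
        assert (t.te_class, t.te_family, t.te_subtype) == ("SINE", "B2", "B3A")
        assert len(t.interval) == 180

    def test_repeatmasker_one_based_conversion_and_split(self, tmp_path):
        row = ("239 22.9 5.0 3.5 chr1 501 680 (1000) + B3 SINE/B2 "
               "1 180 (0) 1\n")
        p = write(tmp_path, "rm.out", row)
        (t,) = genomic_io.read_te_annotation(p, "repeatmasker_out")
        assert (t.interval.start, t.interval.end) == (500, 680)
        assert (t.te_class, t.te_family, t.te_subtype) == ("SINE", "B2", "B3")

    def test_unsplittable_class_family_warns_and_copies(self, tmp_path):
        row = "239 22.9 5.0 3.5 chr1 501 680 (1000) + Poly_A Low_complexity 1 180 (0) 1\n"
        p = write(tmp_path, "rm.out", row)
        with pytest.warns(UserWarning, match="no '/'"):
            (t,) = genomic_io.read_te_annotation(p, "repeatmasker_out")
        assert t.te_class == t.te_family == "Low_complexity"


class TestLoops:
    def test_anchor_canonicalization(self, tmp_path):
        p = write(tmp_path, "l.bedpe", "chr1\t90000\t95000\tchr1\t1000\t6000\n")
        (lp,), skipped = genomic_io.read_loops(p, genotype="WT")
        assert lp.anchorL.start == 1000 and lp.anchorR.start == 90000
        assert skipped == 0

    def test_interchromosomal_skipped_with_count(self, tmp_path):
        p = write(tmp_path, "l.bedpe",
                  "chr1\t0\t100\tchr2\t500\t600\nchr1\t0\t100\tchr1\t500\t600\n"
                  "chr1\t900\t950\tchr1\t2000\t2100\n")
        with pytest.warns(UserWarning, match="inter-chromosomal"):
            loops, skipped = genomic_io.read_loops(p, genotype="KO")
        assert len(loops) == 2 and skipped == 1

    def test_bad_anchor_raises(self, tmp_path):
        p = write(tmp_path, "l.bedpe", "chr1\t100\t100\tchr1\t500\t600\n")
        with pytest.raises(ParseError):
            genomic_io.read_loops(p)


class TestCpGTable:
    GROUPS = {"WT_1": "WT", "KO_1": "KO"}

    def test_beta_retrievable(self, tmp_path):
        p = write(tmp_path, "c.tsv",
                  "chrom\tpos\tWT_1_meth\tWT_1_total\tKO_1_meth\tKO_1_total\n"
                  "chr1\t50\t3\t4\t1\t4\n")
        (r,) = genomic_io.read_cpg_table(p, self.GROUPS)
        assert r.beta("WT_1") == pytest.approx(0.75)

    def test_duplicate_positions_rejected(self, tmp_path):
        p = write(tmp_path, "c.tsv",
                  "chrom\tpos\tWT_1_meth\tWT_1_total\tKO_1_meth\tKO_1_total\n"
                  "chr1\t50\t3\t4\t1\t4\nchr1\t50\t2\t4\t1\t4\n")
        with pytest.raises(ParseError, match="duplicate"):
            genomic_io.read_cpg_table(p, self.GROUPS)

    def test_meth_exceeding_total_rejected(self, tmp_path):
        p = write(tmp_path, "c.tsv",
                  "chrom\tpos\tWT_1_meth\tWT_1_total\tKO_1_meth\tKO_1_total\n"
                  "chr1\t50\t5\t4\t1\t4\n")
        with pytest.raises(ParseError, match="methylated > total"):
            genomic_io.read_cpg_table(p, self.GROUPS)

    def test_unmapped_sample_rejected(self, tmp_path):
        p = write(tmp_path, "c.tsv",
                  "chrom\tpos\tX_meth\tX_total\nchr1\t50\t1\t4\n")
        with pytest.raises(SchemaError, match="group map"):
            genomic_io.read_cpg_table(p, self.GROUPS)

    def test_empty_table_warns(self, tmp_path):
        p = write(tmp_path, "c.tsv", "chrom\tpos\tWT_1_meth\tWT_1_total\n")
        with pytest.warns(UserWarning, match="empty"):
            assert genomic_io.read_cpg_table(p, self.GROUPS) == []


class TestRoundTrips:
    def test_intervals(self, tmp_path):
        ivs = [GenomicInterval("chr1", 5, 10, "+", "a", 2.0),
               GenomicInterval("chr2", 0, 7, "-", "b", None)]
        p = tmp_path / "r.bed"
        genomic_io.write_regions(p, ivs)
        back = genomic_io.read_regions(p, "bed")
        assert [(i.chrom, i.start, i.end, i.strand, i.name) for i in back] == \
            [(i.chrom, i.start, i.end, i.strand, i.name) for i in ivs]

    def test_loops(self, tmp_path):
        loops = [Loop(GenomicInterval("chr1", 0, 100),
                      GenomicInterval("chr1", 900, 1000), "WT")]
        p = tmp_path / "l.bedpe"
        genomic_io.write_loops(p, loops)
        back, _ = genomic_io.read_loops(p)
        assert back == loops

    def test_cpg(self, tmp_path):
        recs = [CpGRecord("chr1", 10, {"WT_1": (2, 4), "KO_1": (0, 3)}),
                CpGRecord("chr1", 90, {"WT_1": (1, 2), "KO_1": (3, 3)})]
        p = tmp_path / "c.tsv"
        genomic_io.write_cpg_table(p, recs)
        assert genomic_io.read_cpg_table(
            p, {"WT_1": "WT", "KO_1": "KO"}) == recs

    def test_pwm(self, tmp_path):
        from teloopkit.synthetic import default_ctcf_pwm

        pwm = default_ctcf_pwm()
        p = tmp_path / "m.jaspar"
        genomic_io.write_pwm_jaspar(p, pwm)
        back = genomic_io.read_pwm_jaspar(p)
        assert back.width == pwm.width
        assert np.allclose(back.probs, pwm.probs, atol=1e-4)

    def test_bundle_files_parse(self, bundle, bundle_dir):
        te = genomic_io.read_te_annotation(bundle_dir / "te.tsv")
        assert len(te) == len(bundle.te)
        diff = genomic_io.read_regions(bundle_dir / "atac_diff.tsv", "diff_table")
        assert len(diff) == len(bundle.atac_diff)
        assert (sorted(r.direction for r in diff)
                == sorted(r.direction for r in bundle.atac_diff))
        wt, _ = genomic_io.read_loops(bundle_dir / "wt.bedpe")
        assert len(wt) == len(bundle.wt_loops)
        genes = genomic_io.read_genes(bundle_dir / "genes.tsv")
        assert len(genes) == len(bundle.genes)
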