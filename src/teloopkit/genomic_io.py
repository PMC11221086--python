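"""Readers and writers for the text formats the pipeline touches.

Everything is normalized at this boundary to 0-based half-open coordinates
and sorted by (chrom, start); downstream modules assume sortedness.
RepeatMasker ``.out`` begins are 1-based and converted here.  All writers
emit tab-separated UTF-8 with a single ``#``-prefixed header line.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    DEFAULT_ALPHA,
    DEFAULT_LFC,
    CpGRecord,
    DifferentialRegion,
    GenomicInterval,
    Loop,
    PWM,
    TEElement,
    classify_direction,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed record (bad coordinates, counts, etc.)."""


class SchemaError(ValueError):
    """A structurally invalid file (missing columns, unknown samples...)."""


def _data_lines(path):
    """Yield (line_number, fields) skipping comments/track/browser lines."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if (not line.strip() or line.startswith("#")
                    or line.startswith("track") or line.startswith("browser")):
                continue
            yield lineno, line.split("\t")


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end)


# ---------------------------------------------------------------------------
# regions

def read_regions(path, format: str = "bed",
                 alpha: float = DEFAULT_ALPHA, lfc: float = DEFAULT_LFC):
    """Read a region file.

    Parameters
    ----------
    format
        ``bed`` (BED3/6), ``narrowPeak`` (BED6+4), or ``diff_table`` (TSV
        with header columns chrom, start, end, log2fc, fdr).  ``diff_table``
        returns :class:`DifferentialRegion` with directions assigned by the
        configured thresholds; the others return :class:`GenomicInterval`.
    """
    if format in ("bed", "narrowPeak"):
        out = []
        for lineno, f in _data_lines(path):
            if len(f) < 3:
                raise SchemaError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from e
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            if format == "narrowPeak" and len(f) >= 7:
                # narrowPeak carries signalValue in column 7; prefer it.
                score = float(f[6])
            out.append(GenomicInterval(f[0], start, end, strand, name, score))
        return sorted(out, key=_sort_key)

    if format == "diff_table":
        df = pd.read_csv(path, sep="\t", comment=None)
        df.columns = [c.lstrip("#") for c in df.columns]
        required = {"chrom", "start", "end", "log2fc", "fdr"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: diff_table missing columns {sorted(missing)}")
        out = []
        for row in df.itertuples(index=False):
            start, end = int(row.start), int(row.end)
            if start >= end:
                raise ParseError(f"{path}: start >= end at {row.chrom}:{start}")
            name = str(row.name) if "name" in df.columns else None
            iv = GenomicInterval(str(row.chrom), start, end, name=name)
            lf, q = float(row.log2fc), float(row.fdr)
            out.append(DifferentialRegion(iv, lf, q, classify_direction(lf, q, alpha, lfc)))
        return sorted(out, key=lambda r: _sort_key(r.interval))

    raise ValueError(f"unknown region format {format!r}")


def write_regions(path, regions) -> None:
    """Write intervals or differential regions as a headered TSV/BED hybrid."""
    with open(path, "wt", encoding="utf-8") as fh:
        if regions and isinstance(regions[0], DifferentialRegion):
            fh.write("#chrom\tstart\tend\tname\tlog2fc\tfdr\tdirection\n")
            for r in regions:
                iv = r.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                         f"{r.log2fc:.6g}\t{r.fdr:.6g}\t{r.direction}\n")
        else:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for iv in regions:
                score = "." if iv.score is None else f"{iv.score:.6g}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                         f"{score}\t{iv.strand}\n")


def read_diff_regions(path, alpha: float = DEFAULT_ALPHA, lfc: float = DEFAULT_LFC):
    """Read back a file written by :func:`write_regions` for differential regions."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    if "direction" in df.columns:
        out = []
        for row in df.itertuples(index=False):
            name = None if str(row.name) == "." else str(row.name)
            iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end), name=name)
            out.append(DifferentialRegion(iv, float(row.log2fc), float(row.fdr),
                                          str(row.direction)))
        return sorted(out, key=lambda r: _sort_key(r.interval))
    return read_regions(path, "diff_table", alpha, lfc)


# ---------------------------------------------------------------------------
# TE annotation

def read_te_annotation(path, format: str = "te_bed"):
    """Read a TE annotation as a list of :class:`TEElement`.

    ``te_bed`` columns: chrom, start, end, te_class, te_family, te_subtype.
    ``repeatmasker_out`` is the standard 15-column RepeatMasker layout
    (1-based begin, converted here); its class/family column is split on
    "/" and the repeat name becomes the subtype.
    """
    out = []
    if format == "te_bed":
        for lineno, f in _data_lines(path):
            if len(f) < 6:
                raise SchemaError(f"{path}:{lineno}: te_bed needs 6 columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            out.append(TEElement(GenomicInterval(f[0], start, end), f[3], f[4], f[5]))
    elif format == "repeatmasker_out":
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                f = raw.split()
                # header block: two banner lines + blank
                if not f or not f[0].lstrip("-").isdigit():
                    continue
                if len(f) < 11:
                    raise SchemaError(f"{path}:{lineno}: short RepeatMasker row")
                chrom, begin, end = f[4], int(f[5]), int(f[6])
                start = begin - 1  # 1-based begin -> 0-based start
                if start >= end:
                    raise ParseError(f"{path}:{lineno}: start >= end")
                subtype = f[9]
                cls_fam = f[10]
                if "/" in cls_fam:
                    te_class, te_family = cls_fam.split("/", 1)
                else:
                    te_class = te_family = cls_fam
                    warnings.warn(
                        f"{path}:{lineno}: class/family field {cls_fam!r} has no '/'; "
                        "family set to class")
                strand = "+" if f[8] == "+" else "-"
                out.append(TEElement(GenomicInterval(chrom, start, end, strand),
                                     te_class, te_family, subtype))
    else:
        raise ValueError(f"unknown TE format {format!r}")
    return sorted(out, key=lambda t: _sort_key(t.interval))


def write_te_annotation(path, elements) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tte_class\tte_family\tte_subtype\n")
        for t in elements:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{t.te_class}\t{t.te_family}\t{t.te_subtype}\n")


# ---------------------------------------------------------------------------
# loops (BEDPE)

def read_loops(path, genotype: str | None = None):
    """Read a BEDPE loop list; returns (loops, n_skipped_interchromosomal).

    Anchors are canonically ordered on read (left anchor starts first).
    The genotype is taken from column 7 unless supplied as an argument.
    """
    loops: list[Loop] = []
    skipped = 0
    for lineno, f in _data_lines(path):
        if len(f) < 6:
            raise SchemaError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
        c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
        if s1 >= e1 or s2 >= e2:
            raise ParseError(f"{path}:{lineno}: start >= end in an anchor")
        if c1 != c2:
            skipped += 1
            warnings.warn(f"{path}:{lineno}: inter-chromosomal loop skipped")
            continue
        a1 = GenomicInterval(c1, s1, e1)
        a2 = GenomicInterval(c2, s2, e2)
        if a2.start < a1.start:
            a1, a2 = a2, a1
        gt = genotype if genotype is not None else (f[6] if len(f) > 6 else "NA")
        loops.append(Loop(a1, a2, gt))
    if skipped:
        logger.info("%s: skipped %d inter-chromosomal rows", path, skipped)
    loops.sort(key=lambda lp: (_sort_key(lp.anchorL), lp.anchorR.start))
    return loops, skipped


def write_loops(path, loops) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tgenotype\n")
        for lp in loops:
            a, b = lp.anchorL, lp.anchorR
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                     f"{lp.genotype}\n")


# ---------------------------------------------------------------------------
# CpG methylation table

def read_cpg_table(path, group_map: dict[str, str]):
    """Read a per-CpG counts table.

    The header names samples as ``<sample>_meth`` / ``<sample>_total`` column
    pairs after ``chrom`` and ``pos``.  Every sample must appear in
    ``group_map`` (values WT or KO).  Records are returned sorted by
    (chrom, pos); duplicate positions are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    if df.empty:
        warnings.warn(f"{path}: empty CpG table")
        return []
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise SchemaError(f"{path}: CpG table needs chrom and pos columns")
    samples = sorted({c[:-5] for c in df.columns if c.endswith("_meth")})
    if not samples:
        raise SchemaError(f"{path}: no <sample>_meth columns found")
    for s in samples:
        if f"{s}_total" not in df.columns:
            raise SchemaError(f"{path}: sample {s} lacks a _total column")
        if s not in group_map:
            raise SchemaError(f"{path}: sample {s} missing from the group map")
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise ParseError(f"{path}: duplicate (chrom, pos) rows")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        counts = {}
        for s in samples:
            m, t = int(d[f"{s}_meth"]), int(d[f"{s}_total"])
            if m > t:
                raise ParseError(
                    f"{path}: methylated > total for {s} at {d['chrom']}:{d['pos']}")
            counts[s] = (m, t)
        records.append(CpGRecord(str(d["chrom"]), int(d["pos"]), counts))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_cpg_table(path, records) -> None:
    if not records:
        Path(path).write_text("#chrom\tpos\n", encoding="utf-8")
        return
    samples = sorted(records[0].samples)
    cols = "\t".join(f"{s}_meth\t{s}_total" for s in samples)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#chrom\tpos\t{cols}\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            vals = "\t".join(f"{r.samples[s][0]}\t{r.samples[s][1]}" for s in samples)
            fh.write(f"{r.chrom}\t{r.pos}\t{vals}\n")


# ---------------------------------------------------------------------------
# genes, DEGs, bedGraph, PWM

def read_genes(path):
    """Read a gene model TSV (chrom, start, end, strand, name) as intervals."""
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 5:
            raise SchemaError(f"{path}:{lineno}: gene table needs 5 columns")
        if f[3] not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: gene strand must be + or -")
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), f[3], f[4]))
    return sorted(out, key=_sort_key)


def write_genes(path, genes) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tname\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.name}\n")


def read_deg_table(path) -> pd.DataFrame:
    """Read a DEG TSV with columns gene, log2fc, p."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = {"gene", "log2fc", "p"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: DEG table missing columns {sorted(missing)}")
    return df


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame sorted by (chrom, start)."""
    rows = []
    for lineno, f in _data_lines(path):
        if len(f) < 4:
            raise SchemaError(f"{path}:{lineno}: bedGraph needs 4 columns")
        start, end = int(f[1]), int(f[2])
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end")
        rows.append((f[0], start, end, float(f[3])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_bedgraph(path, df: pd.DataFrame) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tvalue\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


def read_pwm_jaspar(path) -> PWM:
    """Read a JASPAR-style count matrix, e.g. ``A [ 3 10 ... ]`` lines.

    Counts are normalized per position; a bare 4-line numeric layout
    (A/C/G/T order) is also accepted.
    """
    rows: dict[str, list[float]] = {}
    order = []
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(">") or line.startswith("#"):
                continue
            base = line[0].upper()
            body = line[1:] if base in "ACGT" else line
            if base not in "ACGT":
                base = "ACGT"[len(order)]
            vals = [float(x) for x in
                    body.replace("[", " ").replace("]", " ").split()]
            rows[base] = vals
            order.append(base)
    if set(rows) != set("ACGT"):
        raise SchemaError(f"{path}: PWM must define rows for A, C, G and T")
    mat = np.array([rows[b] for b in "ACGT"], dtype=float).T  # (width, 4)
    totals = mat.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ParseError(f"{path}: PWM position with non-positive total")
    return PWM(mat / totals)


def write_pwm_jaspar(path, pwm: PWM, name: str = "motif", scale: float = 100.0) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate("ACGT"):
            vals = " ".join(f"{v * scale:.2f}" for v in pwm.probs[:, i])
            fh.write(f"{base} [ {vals} ]\n")


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
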