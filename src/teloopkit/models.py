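"""Domain types shared across the pipeline.

All coordinates are 0-based half-open.  Every module consumes and produces
these types (or pandas DataFrames of them), so coordinate conventions are
settled here once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")

#: Default significance threshold on FDR for differential regions.
DEFAULT_ALPHA = 0.05
#: Default absolute log2 fold-change threshold (1.5-fold).
DEFAULT_LFC = 0.585


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic region; the universal currency of the pipeline."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class TEElement:
    """A transposable-element copy with its class/family/subtype hierarchy.

    Example hierarchy for a rodent B2 SINE: (``SINE``, ``B2``, ``B3A``).
    """

    interval: GenomicInterval
    te_class: str
    te_family: str
    te_subtype: str

    def __post_init__(self) -> None:
        if not (self.te_class and self.te_family and self.te_subtype):
            raise ValueError("TE hierarchy fields must be non-empty")


def classify_direction(log2fc: float, fdr: float,
                       alpha: float = DEFAULT_ALPHA,
                       lfc: float = DEFAULT_LFC) -> str:
    """Label a differential region up/down/ns by FDR and log2 fold-change."""
    if fdr < alpha and log2fc >= lfc:
        return "up"
    if fdr < alpha and log2fc <= -lfc:
        return "down"
    return "ns"


@dataclass(frozen=True, slots=True)
class DifferentialRegion:
    """A peak with differential statistics (KO vs WT) and a direction label."""

    interval: GenomicInterval
    log2fc: float
    fdr: float
    direction: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must lie in [0,1], got {self.fdr}")
        if self.direction not in ("up", "down", "ns"):
            raise ValueError(f"direction must be up/down/ns, got {self.direction!r}")


@dataclass(frozen=True, slots=True)
class CpGRecord:
    """Per-CpG methylated/total read counts across samples.

    ``samples`` maps sample name to ``(methylated_reads, total_reads)``.
    """

    chrom: str
    pos: int
    samples: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (m, t) in self.samples.items():
            if m < 0 or t < 0 or m > t:
                raise ValueError(
                    f"sample {name} at {self.chrom}:{self.pos}: "
                    f"need 0 <= methylated ({m}) <= total ({t})"
                )

    def beta(self, sample: str) -> float:
        m, t = self.samples[sample]
        return m / t if t else float("nan")


@dataclass(frozen=True, slots=True)
class Loop:
    """An intra-chromosomal chromatin loop: ordered anchor pair plus genotype."""

    anchorL: GenomicInterval
    anchorR: GenomicInterval
    genotype: str

    def __post_init__(self) -> None:
        if self.anchorL.chrom != self.anchorR.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchorL.start >= self.anchorR.start:
            raise ValueError("anchors must be canonically ordered (left before right)")


@dataclass(frozen=True, slots=True)
class OverlapRule:
    """Reciprocal-fraction overlap semantics (bedtools ``-f/-F/-e`` style).

    An overlap qualifies when it covers at least ``min_frac_query`` of the
    query and at least ``min_frac_target`` of the target; with
    ``either_satisfies`` the two conditions are OR-ed instead of AND-ed.
    """

    min_frac_query: float = 0.5
    min_frac_target: float = 0.5
    either_satisfies: bool = True

    def __post_init__(self) -> None:
        for f in (self.min_frac_query, self.min_frac_target):
            if not (0.0 < f <= 1.0):
                raise ValueError(f"overlap fractions must lie in (0,1], got {f}")

    def qualifies(self, overlap: int, len_q: int, len_t: int) -> bool:
        ok_q = overlap >= self.min_frac_query * len_q
        ok_t = overlap >= self.min_frac_target * len_t
        return (ok_q or ok_t) if self.either_satisfies else (ok_q and ok_t)


#: Rule with vanishing fractions: any 1-bp overlap qualifies.
ANY_OVERLAP = OverlapRule(min_frac_query=1e-9, min_frac_target=1e-9,
                          either_satisfies=True)


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """One category's 2x2 enrichment outcome (count or cumulative-length mode)."""

    level: str
    category: str
    mode: str
    observed_in: int
    observed_out: int
    background_in: int
    background_out: int
    fold_enrichment: float
    p: float
    p_adj: float


@dataclass(frozen=True, slots=True)
class PWM:
    """Position weight matrix: per-position base probabilities plus background.

    ``probs`` has shape (width, 4) over the alphabet ACGT and each row sums
    to 1 after pseudocount; ``background`` sums to 1.
    """

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("PWM probs must have shape (width, 4) with width >= 1")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, pseudocount: float = 0.01) -> np.ndarray:
        """(width, 4) log2-odds matrix after adding ``pseudocount`` per cell."""
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        p = self.probs + pseudocount
        p /= p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background[None, :])

    def max_score(self, pseudocount: float = 0.01) -> float:
        return float(self.log_odds(pseudocount).max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True, slots=True)
class DMR:
    """A differentially methylated region (KO - WT)."""

    interval: GenomicInterval
    n_cpg: int
    mean_diff: float
    avg_meth: float
    status: str

    def __post_init__(self) -> None:
        if self.status not in ("hyper", "hypo"):
            raise ValueError("status must be hyper or hypo")
        if (self.mean_diff < 0) != (self.status == "hypo"):
            raise ValueError("status inconsistent with sign of mean_diff")


@dataclass(frozen=True, slots=True)
class QuadrantRecord:
    """A (DMR, differential ATAC peak) overlapping pair placed in a quadrant.

    Quadrants follow the (accessibility log2FC, methylation difference) sign
    convention: Q1 (+,+), Q2 (-,+), Q3 (-,-), Q4 (+,-); the fourth quadrant
    is hypomethylated and more accessible.
    """

    dmr: DMR
    atac: DifferentialRegion
    quadrant: int
    is_b2: bool
    is_significant: bool

    def __post_init__(self) -> None:
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError("quadrant must be in {1,2,3,4}")


@dataclass(frozen=True, slots=True)
class MotifHit:
    """Best log-odds PWM hit within one region (max-score convention)."""

    region_index: int
    best_score: float
    strand: str | None
    offset: int | None
    passes: bool
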