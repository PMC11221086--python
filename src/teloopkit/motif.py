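"""Log-odds PWM scanning (best-hit / max-score convention) and motif enrichment.

Scores are log2(p/bg) sums over the motif window; the minus strand scores
the reverse complement.  Ties break toward the smaller offset, then the
plus strand.  Windows containing N are skipped.
"""

from __future__ import annotations

import numpy as np

from .models import MotifHit, PWM
from .te_enrichment import fisher_test

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence to 0..3 (ACGT) with 4 for N/unknown."""
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _window_scores(code: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every window of width ``lo.shape[0]``; NaN where the window has N."""
    w = lo.shape[0]
    n_win = code.size - w + 1
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    padded = np.vstack([lo.T, np.zeros(w)])  # row 4 scores N as 0, masked below
    for j in range(w):
        col = code[j:j + n_win]
        scores += padded[col, j]
        bad |= col == 4
    scores[bad] = np.nan
    return scores


def scan_best(pwm: PWM, sequence: str, pseudocount: float = 0.01,
              threshold: float | None = None,
              region_index: int = 0) -> MotifHit:
    """Best PWM hit over both strands of ``sequence``.

    ``threshold`` defaults to 80% of the PWM's maximum attainable score;
    ``passes`` reports whether the best score reaches it.  If every window
    contains N the hit has ``passes=False`` and no strand/offset.
    """
    lo = pwm.log_odds(pseudocount)
    w = pwm.width
    if len(sequence) < w:
        raise ValueError(f"sequence length {len(sequence)} < motif width {w}")
    if threshold is None:
        threshold = 0.8 * pwm.max_score(pseudocount)

    fwd = _window_scores(encode(sequence), lo)
    # minus strand: score the reverse complement, then map its offsets back
    # to forward coordinates (offset' = L - w - offset).
    rev_raw = _window_scores(encode(revcomp(sequence)), lo)
    rev = rev_raw[::-1]

    # flatten offset-major with + before -, so argmax realizes the tie-break
    stacked = np.where(np.isnan(np.column_stack([fwd, rev])), -np.inf,
                       np.column_stack([fwd, rev])).ravel()
    if not np.isfinite(stacked).any():
        return MotifHit(region_index, float("-inf"), None, None, False)
    flat = int(stacked.argmax())
    offset, strand = divmod(flat, 2)
    best_score = float(stacked[flat])
    return MotifHit(region_index, best_score, "+-"[strand], offset,
                    best_score >= threshold)


def scan_regions(pwm: PWM, regions, fasta, pseudocount: float = 0.01,
                 threshold: float | None = None):
    """Best hit per region against an indexed FASTA (pyfaidx or dict)."""
    hits = []
    for i, region in enumerate(regions):
        iv = getattr(region, "interval", region)
        seq = _fetch(fasta, iv)
        hits.append(scan_best(pwm, seq, pseudocount, threshold, region_index=i))
    return hits


def _fetch(fasta, iv) -> str:
    if isinstance(fasta, dict):
        chrom = fasta.get(iv.chrom)
        if chrom is None or iv.end > len(chrom):
            raise ValueError(
                f"region {iv.chrom}:{iv.start}-{iv.end} outside FASTA bounds")
        return chrom[iv.start:iv.end]
    rec = fasta[iv.chrom]
    if iv.end > len(rec):
        raise ValueError(f"region {iv.chrom}:{iv.start}-{iv.end} outside FASTA bounds")
    return str(rec[iv.start:iv.end])


def motif_enrichment(foreground, background, fasta, pwm: PWM,
                     threshold: float | None = None,
                     pseudocount: float = 0.01):
    """Fisher enrichment of passing motif hits in foreground vs background.

    Background regions identical in coordinates to a foreground region are
    excluded from the comparison group.
    """
    fg_hits = scan_regions(pwm, foreground, fasta, pseudocount, threshold)
    fg_keys = {(getattr(r, "interval", r).chrom,
                getattr(r, "interval", r).start,
                getattr(r, "interval", r).end) for r in foreground}
    bg_only = [r for r in background
               if (getattr(r, "interval", r).chrom,
                   getattr(r, "interval", r).start,
                   getattr(r, "interval", r).end) not in fg_keys]
    bg_hits = scan_regions(pwm, bg_only, fasta, pseudocount, threshold)
    a = sum(h.passes for h in fg_hits)
    b = len(fg_hits) - a
    c = sum(h.passes for h in bg_hits)
    d = len(bg_hits) - c
    if c + d == 0:  # foreground == background: degenerate comparison
        odds, p = float("nan"), 1.0
    else:
        odds, p = fisher_test(a, b, c, d)
    # fold enrichment against the FULL background (which contains the
    # foreground), so identical sets give exactly 1
    n_fg = len(fg_hits)
    full_in = a + c
    full_tot = n_fg + len(bg_hits)
    if n_fg and full_tot and full_in:
        fold = (a / n_fg) / (full_in / full_tot)
    elif a == 0:
        fold = float("nan")
    else:
        fold = float("inf")
    return {"fg_with_hit": a, "fg_without": b, "bg_with_hit": c, "bg_without": d,
            "fold_enrichment": fold, "odds_ratio": odds, "p": p,
            "fg_hits": fg_hits, "bg_hits": bg_hits}
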