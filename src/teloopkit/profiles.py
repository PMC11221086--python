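"""Aggregate signal over region sets (the scale-regions convention).

The region body is split into a fixed number of equal-as-possible bins and
flanked by fixed-size bins; each bin takes the coverage-weighted mean of a
bedGraph track (missing positions count as 0).  Minus-strand regions are
reversed so every row reads 5' to 3'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import make_windows
from .models import GenomicInterval


@dataclass
class SignalMatrix:
    regions: list
    n_flank_bins_up: int
    n_body_bins: int
    n_flank_bins_down: int
    bin_size: int
    values: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return self.n_flank_bins_up + self.n_body_bins + self.n_flank_bins_down


class _Track:
    """Per-chromosome piecewise-constant track with interval integrals."""

    def __init__(self, df: pd.DataFrame):
        self._chroms = {}
        for chrom, sub in df.groupby("chrom"):
            sub = sub.sort_values("start")
            self._chroms[chrom] = (sub["start"].to_numpy(),
                                   sub["end"].to_numpy(),
                                   sub["value"].to_numpy(float))

    def integral(self, chrom: str, a: int, b: int) -> float:
        """Integral of the track over [a, b); uncovered bp contribute 0."""
        if chrom not in self._chroms or a >= b:
            return 0.0
        starts, ends, vals = self._chroms[chrom]
        lo = np.searchsorted(ends, a, side="right")
        hi = np.searchsorted(starts, b, side="left")
        if lo >= hi:
            return 0.0
        ov = (np.minimum(ends[lo:hi], b) - np.maximum(starts[lo:hi], a)).clip(min=0)
        return float((ov * vals[lo:hi]).sum())


def compute_matrix(track: pd.DataFrame, regions, *,
                   flank_up: int = 1000, flank_down: int = 1000,
                   body_bins: int = 100, bin_size: int = 10,
                   skip_zeros: bool = False,
                   chrom_sizes: dict[str, int] | None = None) -> SignalMatrix:
    """Scaled-body signal matrix with fixed flank bins.

    ``track`` is a bedGraph DataFrame (chrom, start, end, value) whose rows
    do not overlap one another.  Flank windows extending past the
    chromosome bounds are clipped (a warning is raised); clipped or
    zero-length bins take value 0.
    """
    trk = _Track(track)
    n_up = flank_up // bin_size
    n_down = flank_down // bin_size
    rows, kept = [], []
    for region in regions:
        iv = getattr(region, "interval", region)
        chrom_len = chrom_sizes.get(iv.chrom) if chrom_sizes else None
        bins: list[tuple[int, int]] = []
        for k in range(n_up):
            bins.append((iv.start - flank_up + k * bin_size,
                         iv.start - flank_up + (k + 1) * bin_size))
        for w in make_windows(iv, body_bins):
            bins.append((w.start, w.end))
        for k in range(n_down):
            bins.append((iv.end + k * bin_size, iv.end + (k + 1) * bin_size))
        if bins[0][0] < 0 or (chrom_len is not None and bins[-1][1] > chrom_len):
            warnings.warn(
                f"region {iv.chrom}:{iv.start}-{iv.end} flanks extend past "
                "chromosome bounds; clipped")
        row = np.empty(len(bins))
        for j, (a, b) in enumerate(bins):
            a = max(a, 0)
            if chrom_len is not None:
                b = min(b, chrom_len)
            row[j] = trk.integral(iv.chrom, a, b) / (b - a) if b > a else 0.0
        if iv.strand == "-":
            row = row[::-1]
        if skip_zeros and not row.any():
            continue
        rows.append(row)
        kept.append(region)
    values = np.vstack(rows) if rows else np.empty((0, n_up + body_bins + n_down))
    return SignalMatrix(kept, n_up, body_bins, n_down, bin_size, values)


def mean_profile(matrix: SignalMatrix) -> np.ndarray:
    """Per-bin mean over regions."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty signal matrix")
    return matrix.values.mean(axis=0)


def matrix_to_frame(matrix: SignalMatrix) -> pd.DataFrame:
    cols = ([f"up{i+1}" for i in range(matrix.n_flank_bins_up)]
            + [f"body{i+1}" for i in range(matrix.n_body_bins)]
            + [f"down{i+1}" for i in range(matrix.n_flank_bins_down)])
    names = []
    for r in matrix.regions:
        iv = getattr(r, "interval", r)
        names.append(f"{iv.chrom}:{iv.start}-{iv.end}")
    return pd.DataFrame(matrix.values, columns=cols, index=names)
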