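"""Resampling-from-universe permutation tests for region-set association.

Each iteration redraws |query| regions from the universe uniformly without
replacement (the regioneR ``resampleRegions`` scheme) and recomputes the
statistic: ``num_overlaps`` (regions overlapping >= 1 feature by >= 1 bp)
or ``mean_distance`` (mean midpoint distance to the nearest feature).  The
empirical p is +1-smoothed so it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import distance_to_nearest, overlaps_any

STATISTICS = ("num_overlaps", "mean_distance")


@dataclass(frozen=True)
class PermutationResult:
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    n_iter: int
    alternative: str
    seed: int


def _coord_key(iv):
    return (iv.chrom, iv.start, iv.end)


def perm_test(query, universe, features, statistic: str = "num_overlaps",
              n_iter: int = 200, alternative: str = "greater",
              seed: int = 0) -> PermutationResult:
    """Permutation test of ``query`` against ``features``, resampling from
    ``universe`` (which must contain every query region by coordinates)."""
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be greater or less")
    if not (1 <= len(query) <= len(universe)):
        raise ValueError("need |universe| >= |query| >= 1")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    uni_keys = {_coord_key(getattr(r, "interval", r)) for r in universe}
    q_ivs = [getattr(r, "interval", r) for r in query]
    for iv in q_ivs:
        if _coord_key(iv) not in uni_keys:
            raise ValueError(
                f"query region {iv.chrom}:{iv.start}-{iv.end} is not in the universe")

    u_ivs = [getattr(r, "interval", r) for r in universe]
    f_ivs = sorted((getattr(r, "interval", r) for r in features),
                   key=lambda iv: (iv.chrom, iv.start))
    if statistic == "mean_distance" and not f_ivs:
        raise ValueError("mean_distance requires >= 1 feature")

    # per-universe-region statistic, computed once
    u_sorted_order = sorted(range(len(u_ivs)),
                            key=lambda i: (u_ivs[i].chrom, u_ivs[i].start))
    u_sorted = [u_ivs[i] for i in u_sorted_order]
    if statistic == "num_overlaps":
        flags_sorted = overlaps_any(u_sorted, f_ivs)
        per_region = np.empty(len(u_ivs))
        per_region[np.array(u_sorted_order)] = flags_sorted.astype(float)
    else:
        points = [(iv.chrom, iv.midpoint) for iv in f_ivs]
        dists = distance_to_nearest(u_sorted, points)
        if any(d is None for d in dists):
            raise ValueError(
                "a universe region lies on a chromosome without features; "
                "mean_distance is undefined there")
        per_region = np.empty(len(u_ivs))
        per_region[np.array(u_sorted_order)] = np.asarray(dists, dtype=float)

    key_to_index: dict[tuple, int] = {}
    for i, iv in enumerate(u_ivs):
        key_to_index.setdefault(_coord_key(iv), i)
    q_idx = np.array([key_to_index[_coord_key(iv)] for iv in q_ivs])
    nq = len(q_idx)

    def stat_of(values: np.ndarray) -> float:
        return float(values.sum()) if statistic == "num_overlaps" \
            else float(values.mean())

    observed = stat_of(per_region[q_idx])

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.choice(len(u_ivs), size=nq, replace=False)
        null[it] = stat_of(per_region[idx])

    if alternative == "greater":
        extreme = int((null >= observed).sum())
    else:
        extreme = int((null <= observed).sum())
    p = (1 + extreme) / (n_iter + 1)
    null_mean = float(null.mean())
    null_sd = float(null.std())
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    return PermutationResult(statistic, observed, null_mean, null_sd, z, p,
                             n_iter, alternative, seed)
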