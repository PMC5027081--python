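"""Circular binary segmentation (CBS) of normalized probe ratios.

Each chromosome's probe series is treated as a circle and recursively
split: the maximal two-arc t-statistic over all arc pairs is compared with
its permutation null; a significant arc contributes its endpoints as
change-points, and the resulting sub-segments are re-examined until no
significant split remains. On a circle the complement of an arc is the
wrapped arc, and the two-sample t is antisymmetric under swapping arc and
complement, so maximizing |t| over linear index pairs (i, j) covers every
circular arc without explicit wrap-around.

The statistic for the arc x[i:j] against its complement is

    t(i, j) = (mean_in - mean_out) / (s * sqrt(1/n_in + 1/n_out))

with s the segment-wide sample SD; s is permutation-invariant, so the
permutation distribution of max|t| is unaffected by this choice of scale.
With cumulative sums the statistic reduces to

    |t| = |n * (S_j - S_i) - (j - i) * S_n| / (s * sqrt(n * w * (n - w))),

w = j - i, which is maximized either in one vectorized pass over the
(i, j) grid (small n) or by sweeping arc widths with sliding sums (large
n, O(n) memory). Ties resolve to the first pair in (i, j) scan order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .normalize import NormalizedProfile

__all__ = ["max_circular_t", "cbs_segment"]

_DENSE_LIMIT = 700  # use the O(n^2)-memory grid path below this length


def _pair_denominators(n: int, s: float) -> np.ndarray:
    """(n+1)x(n+1) matrix of t denominators; invalid pairs get +inf."""
    idx = np.arange(n + 1)
    w = idx[None, :] - idx[:, None]  # arc width j - i
    valid = (w >= 1) & (w <= n - 1)
    denom = np.full(w.shape, np.inf)
    wv = w[valid].astype(float)
    denom[valid] = s * np.sqrt(n * wv * (n - wv))
    return denom


def _max_t_dense(cum: np.ndarray, total: float, n: int, denom: np.ndarray):
    num = np.abs(n * (cum[None, :] - cum[:, None]) - (np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None]) * total)
    t = num / denom
    flat = int(np.argmax(t))
    i, j = divmod(flat, n + 1)
    return float(t[i, j]), i, j


def _max_t_sweep(cum: np.ndarray, total: float, n: int, s: float):
    best_t, best_i, best_j = -1.0, 0, 1
    for w in range(1, n):
        arc_sums = cum[w:] - cum[:-w]
        t_w = np.abs(n * arc_sums - w * total) / (s * np.sqrt(n * w * (n - w)))
        k = int(np.argmax(t_w))
        if t_w[k] > best_t + 1e-15:
            best_t, best_i, best_j = float(t_w[k]), k, k + w
    return best_t, best_i, best_j


def max_circular_t(x: np.ndarray) -> tuple[float, int, int] | None:
    """Best circular split of a series: ``(|t|, i, j)`` for arc ``x[i:j]``.

    Returns None for series that cannot be split (fewer than 2 points or
    zero variance).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return None
    s = x.std(ddof=1)
    if s == 0:
        return None
    cum = np.concatenate(([0.0], np.cumsum(x)))
    total = cum[-1]
    if n <= _DENSE_LIMIT:
        return _max_t_dense(cum, total, n, _pair_denominators(n, s))
    return _max_t_sweep(cum, total, n, s)


def _is_significant(
    x: np.ndarray,
    observed_t: float,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
) -> bool:
    """Permutation test of the observed max|t| with an early-exit rule:
    once exceedances guarantee p > alpha the decision cannot change."""
    n = len(x)
    s = x.std(ddof=1)
    total = float(np.sum(x))
    dense = n <= _DENSE_LIMIT
    denom = _pair_denominators(n, s) if dense else None
    stop_at = int(np.floor(alpha * (n_perm + 1)))
    if stop_at < 1:
        return False  # even zero exceedances cannot reach p <= alpha
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        cum = np.concatenate(([0.0], np.cumsum(perm)))
        if dense:
            t, _, _ = _max_t_dense(cum, total, n, denom)
        else:
            t, _, _ = _max_t_sweep(cum, total, n, s)
        if t >= observed_t:
            exceed += 1
            if exceed >= stop_at:
                return False
    return (1 + exceed) / (1 + n_perm) <= alpha


def _segment_one_chrom(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive splitting of one chromosome; returns probe-index intervals."""
    final: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < max(min_width, 2):
            final.append((lo, hi))
            continue
        res = max_circular_t(x[lo:hi])
        if res is None:
            final.append((lo, hi))
            continue
        tmax, i, j = res
        if not _is_significant(x[lo:hi], tmax, n_perm, alpha, rng):
            final.append((lo, hi))
            continue
        cuts = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(cuts, cuts[1:]):
            stack.append((a, b))
    final.sort()
    return _merge_equal_means(x, final)


def _merge_equal_means(
    x: np.ndarray, intervals: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in intervals:
        if merged:
            plo, phi = merged[-1]
            if np.isclose(x[plo:phi].mean(), x[lo:hi].mean(), rtol=1e-9, atol=1e-12):
                merged[-1] = (plo, hi)
                continue
        merged.append((lo, hi))
    return merged


def _bp_boundaries(starts: np.ndarray, chrom_length: int | None) -> np.ndarray:
    """Probe-interval edges: chromosome start, inter-probe midpoints, end."""
    if len(starts) == 1:
        mids = np.array([], dtype=float)
    else:
        mids = (starts[:-1] + starts[1:]) / 2.0
    if chrom_length is None:
        spacing = float(np.median(np.diff(starts))) if len(starts) > 1 else 1.0
        right = starts[-1] + spacing / 2.0
    else:
        right = float(chrom_length)
    return np.concatenate(([0.0], mids, [right]))


def cbs_segment(
    profile: NormalizedProfile | pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: int = 0,
    genome: GenomeModel | None = None,
    value_col: str = "processed_ratio",
) -> pd.DataFrame:
    """Segment a normalized profile chromosome by chromosome.

    Parameters
    ----------
    profile:
        A :class:`~oacgh.normalize.NormalizedProfile` or a probe DataFrame
        with columns ``chrom``, ``start`` and ``value_col``, sorted by
        (chromosome order, start).
    alpha:
        Permutation significance level for accepting a split.
    n_perm:
        Permutations per split decision.
    min_width:
        Chromosomes (or sub-segments) with fewer retained probes are left
        unsplit.
    genome:
        If given, segment bp spans extend to the chromosome ends so the
        segments partition each chromosome exactly.

    Returns a segment table (chrom, start, end, n_probes, seg_mean) whose
    bp spans partition each chromosome at inter-probe midpoints; adjacent
    segments with equal means are merged, and per-chromosome probe counts
    are conserved.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    probes = profile.probes if isinstance(profile, NormalizedProfile) else profile
    rng = np.random.default_rng(seed)
    records = []
    for chrom, group in probes.groupby("chrom", sort=False):
        x = group[value_col].to_numpy(dtype=float)
        starts = group["start"].to_numpy(dtype=float)
        edges = _bp_boundaries(
            starts, genome.lengths[chrom] if genome is not None else None
        )
        for lo, hi in _segment_one_chrom(x, alpha, n_perm, min_width, rng):
            records.append(
                {
                    "chrom": chrom,
                    "start": int(edges[lo]),
                    "end": int(np.ceil(edges[hi])),
                    "n_probes": hi - lo,
                    "seg_mean": float(x[lo:hi].mean()),
                }
            )
    return pd.DataFrame(records)
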