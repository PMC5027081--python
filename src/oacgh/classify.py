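"""Hierarchical clustering and co-clustering subtype classification.

Copy-number profiles segmented independently per sample are made
comparable by projection onto a shared marker grid (1 Mb bins by
default), scaled, and clustered with Ward's minimum-variance criterion on
Euclidean distances. A query sample is classified by clustering it
jointly with a labeled reference cohort, cutting the tree into flat
clusters, and taking the majority subtype among the labeled members of
its cluster; a query stranded in an unlabeled cluster (or a tied vote)
falls back to its nearest labeled neighbor and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist

from .genome import GenomeModel
from .normalize import mean_abs_deviation

DEFAULT_BIN_SIZE = 1_000_000


@dataclass
class Dendrogram:
    """Ward merge tree over named leaves.

    ``linkage`` is a scipy linkage matrix; heights are non-decreasing
    along merges. Ward's method here is the Lance-Williams minimum-
    variance update on (squared) Euclidean distances; merge order is
    deterministic, ties resolving to the lowest pair index.
    """

    linkage: np.ndarray
    leaves: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.leaves[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster ids (1..k) per leaf."""
        if k > len(self.leaves):
            raise ValueError(f"cannot cut {len(self.leaves)} leaves into {k} clusters")
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.leaves, name="cluster")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "count"]
        )


def make_marker_grid(
    genome: GenomeModel,
    bin_size: int = DEFAULT_BIN_SIZE,
    exclude: frozenset[str] | set[str] = frozenset({"X"}),
) -> pd.DataFrame:
    """Non-overlapping, sorted bins covering the non-excluded chromosomes."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    records = []
    for chrom in genome.names:
        if chrom in exclude:
            continue
        length = genome.lengths[chrom]
        edges = np.arange(0, length, bin_size, dtype=np.int64)
        for start in edges:
            records.append(
                {"chrom": chrom, "start": int(start), "end": int(min(start + bin_size, length))}
            )
    return pd.DataFrame(records)


def project_to_grid(segments: pd.DataFrame, grid: pd.DataFrame) -> np.ndarray:
    """Length-weighted mean of segment means per grid bin (0 where empty)."""
    if len(grid) == 0:
        raise ValueError("empty marker grid")
    values = np.zeros(len(grid))
    weights = np.zeros(len(grid))
    grid_chrom = grid["chrom"].to_numpy()
    grid_start = grid["start"].to_numpy()
    grid_end = grid["end"].to_numpy()
    for chrom, segs in segments.groupby("chrom", sort=False):
        on = grid_chrom == chrom
        if not on.any():
            continue
        idx = np.flatnonzero(on)
        for row in segs.itertuples():
            lo = np.maximum(grid_start[idx], row.start)
            hi = np.minimum(grid_end[idx], row.end)
            overlap = np.clip(hi - lo, 0, None)
            values[idx] += row.seg_mean * overlap
            weights[idx] += overlap
    covered = weights > 0
    values[covered] /= weights[covered]
    values[~covered] = 0.0
    return values


def scale_cohort(matrix: pd.DataFrame, mode: str = "per-sample") -> pd.DataFrame:
    """Scale segmented values before clustering.

    ``per-sample``: each row centered at its median and divided by its
    mean absolute deviation (the same robust center/scale used for probe
    normalization). ``per-marker``: column z-scores.
    """
    if mode == "per-sample":
        out = {}
        for sample, row in matrix.iterrows():
            values = row.to_numpy(dtype=float)
            spread = mean_abs_deviation(values)
            if spread == 0:
                raise ValueError(f"sample {sample!r} has zero dispersion; cannot scale")
            out[sample] = (values - np.median(values)) / spread
        return pd.DataFrame.from_dict(out, orient="index", columns=matrix.columns)
    if mode == "per-marker":
        sd = matrix.std(axis=0, ddof=1)
        flat = sd[sd == 0].index.tolist()
        if flat:
            raise ValueError(f"zero-dispersion markers: {flat[:5]}")
        return (matrix - matrix.mean(axis=0)) / sd
    raise ValueError(f"mode must be 'per-sample' or 'per-marker', got {mode!r}")


def ward_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Ward/Euclidean agglomerative tree over the rows of ``matrix``."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    data = matrix.to_numpy(dtype=float)
    if np.isnan(data).any():
        raise ValueError("matrix contains missing values")
    linkage = hierarchy.linkage(data, method="ward")
    return Dendrogram(linkage=linkage, leaves=list(matrix.index))


def cluster_cell_lines(call_matrix: pd.DataFrame) -> Dendrogram:
    """Ward/Euclidean tree over dichotomized {-1, 0, +1} profiles."""
    bad = set(np.unique(call_matrix.to_numpy())) - {-1, 0, 1}
    if bad:
        raise ValueError(f"dichotomized matrix contains non-ternary values: {bad}")
    return ward_cluster(call_matrix)


def assign_subtype(
    matrix: pd.DataFrame,
    labels: pd.Series,
    query_ids: list[str],
    k: int | None = None,
) -> pd.DataFrame:
    """Classify queries by co-clustering with the labeled cohort.

    ``matrix`` holds cohort and query rows (already on a shared grid and
    scaled); ``labels`` indexes the cohort rows only. The joint Ward tree
    is cut into ``k`` flat clusters and each query takes the majority
    subtype of the labeled members of its cluster. No labeled member, or
    a tied vote, falls back to the nearest labeled neighbor (Euclidean)
    with ``fallback=True``.

    The default cut is twice the number of distinct cohort subtypes: a
    cut at exactly the subtype count assumes the top clades align one to
    one with subtypes, but heterogeneous subtypes split while similar
    ones lump together, polluting the vote; a finer cut keeps clusters
    purer and the fallback covers any cluster left without labels.

    Returns one row per query: assigned subtype, cluster id, winning vote
    fraction, and the fallback flag.
    """
    missing = [q for q in query_ids if q not in matrix.index]
    if missing:
        raise ValueError(f"query ids not in matrix: {missing[:5]}")
    if k is None:
        k = min(2 * labels.nunique(), len(matrix))
    if k < 2:
        raise ValueError("k must be >= 2")
    tree = ward_cluster(matrix)
    flat = tree.cut(k)
    labeled_ids = [s for s in matrix.index if s in labels.index]
    records = []
    for q in query_ids:
        cluster = flat[q]
        members = [s for s in labeled_ids if flat[s] == cluster and s != q]
        fallback = False
        vote_fraction = np.nan
        if members:
            votes = labels.loc[members].value_counts()
            top = votes[votes == votes.max()]
            if len(top) == 1:
                assigned = top.index[0]
                vote_fraction = votes.max() / votes.sum()
            else:
                fallback = True
        else:
            fallback = True
        if fallback:
            dists = cdist(
                matrix.loc[[q]].to_numpy(dtype=float),
                matrix.loc[labeled_ids].to_numpy(dtype=float),
            )[0]
            assigned = labels.loc[labeled_ids[int(np.argmin(dists))]]
        records.append(
            {
                "query": q,
                "subtype": assigned,
                "cluster": int(cluster),
                "vote_fraction": vote_fraction,
                "fallback": fallback,
            }
        )
    return pd.DataFrame(records)
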