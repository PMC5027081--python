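"""Companion expression computations on a normalized log2 matrix.

Median centering per array, a variability filter (rows with SD below the
threshold dropped), signed fold change against a pooled baseline, >5-fold
gene lists, unsupervised Ward clustering of samples, and the comparative
Ct (delta-delta-Ct) method for qPCR validation with a designated
reference gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import Dendrogram, ward_cluster

SD_THRESHOLD = 2.0
FOLD_CUTOFF = 5.0


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample column's median (idempotent)."""
    return matrix - matrix.median(axis=0)


def sd_filter(matrix: pd.DataFrame, threshold: float = SD_THRESHOLD) -> pd.DataFrame:
    """Drop rows with limited variation: SD (n-1 denominator) below ``threshold``.

    Rows with SD exactly at the threshold are retained — the filter
    removes strictly-smaller variation. Warns when nothing survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sd = matrix.std(axis=1, ddof=1)
    kept = matrix.loc[sd >= threshold]
    if kept.empty:
        import warnings

        warnings.warn("variability filter removed every row", stacklevel=2)
    return kept


def signed_fold(delta_log2: np.ndarray | float) -> np.ndarray | float:
    """Signed-fold convention: 2^d for d >= 0, -2^(-d) for d < 0.

    A 3-cycle log2 drop reads as -8 ("downregulated 8-fold") rather than
    0.125; magnitudes are always >= 1.
    """
    d = np.asarray(delta_log2, dtype=float)
    out = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    return out if out.shape else float(out)


def fold_change(
    matrix: pd.DataFrame, baseline_samples: list[str]
) -> pd.DataFrame:
    """Per-row signed fold change of each case sample vs the baseline mean.

    ``baseline_samples`` are averaged (log2 scale) to form the reference;
    all other columns are cases. Returns cases-only columns of signed
    folds.
    """
    missing = [s for s in baseline_samples if s not in matrix.columns]
    if missing:
        raise ValueError(f"baseline samples not in matrix: {missing}")
    if not baseline_samples:
        raise ValueError("need at least one baseline sample")
    baseline = matrix[baseline_samples].mean(axis=1)
    cases = [c for c in matrix.columns if c not in baseline_samples]
    delta = matrix[cases].sub(baseline, axis=0)
    return pd.DataFrame(
        signed_fold(delta.to_numpy()), index=matrix.index, columns=cases
    )


def fold_gene_lists(
    folds: pd.DataFrame, cutoff: float = FOLD_CUTOFF
) -> dict[str, dict[str, list[str]]]:
    """Per-case up/down gene lists with |signed fold| above ``cutoff``."""
    out = {}
    for case in folds.columns:
        f = folds[case]
        out[case] = {
            "up": f.index[f > cutoff].tolist(),
            "down": f.index[f < -cutoff].tolist(),
        }
    return out


def cluster_expression(matrix: pd.DataFrame) -> Dendrogram:
    """Unsupervised Ward/Euclidean tree over sample columns."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    return ward_cluster(matrix.T)


def ddct(
    ct: pd.DataFrame,
    target_gene: str,
    case_sample: str,
    reference_gene: str = "RPL32",
    baseline_samples: list[str] | None = None,
) -> float:
    """Comparative-Ct fold change: 2^(-ddCt).

    ``ct`` is a tidy table with columns ``sample``, ``gene``, ``ct``
    (replicate rows allowed; replicates are averaged first). dCt =
    Ct_target - Ct_reference per sample; ddCt subtracts the mean baseline
    dCt; the fold change is 2^(-ddCt). Adding a constant to all Cts of a
    sample (a plate shift) cancels.
    """
    if baseline_samples is None:
        baseline_samples = [
            s for s in ct["sample"].unique() if s != case_sample
        ]
    if not baseline_samples:
        raise ValueError("no baseline samples")
    mean_ct = ct.groupby(["sample", "gene"])["ct"].mean()

    def dct(sample: str) -> float:
        try:
            target = mean_ct[(sample, target_gene)]
            reference = mean_ct[(sample, reference_gene)]
        except KeyError as exc:
            raise ValueError(
                f"sample {sample!r} lacks Ct for gene {exc.args[0][1]!r}"
            ) from None
        return float(target - reference)

    ddct_value = dct(case_sample) - float(np.mean([dct(s) for s in baseline_samples]))
    return float(np.exp2(-ddct_value))
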