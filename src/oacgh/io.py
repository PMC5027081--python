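"""Readers and writers for the pipeline's text formats.

Internal coordinates are 0-based half-open everywhere; SEG files are
written 1-based inclusive (the de facto convention for segmented
copy-number tracks) and BED files 0-based half-open. All tables are plain
tab-delimited text.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .genome import GenomeModel

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "r_signal", "g_signal"]


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    probes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    return probes


def write_genome(genome: GenomeModel, path: str | Path) -> None:
    pd.DataFrame(
        {"chrom": genome.names, "length": [genome.lengths[n] for n in genome.names]}
    ).to_csv(path, sep="\t", index=False)


def read_genome(path: str | Path) -> GenomeModel:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GenomeModel(
        names=tuple(table["chrom"]),
        lengths=dict(zip(table["chrom"], table["length"].astype(int))),
    )


def load_toy_segments() -> pd.DataFrame:
    """Packaged miniature segment table exercising both calling rules."""
    with resources.files("oacgh.data").joinpath("toy_segments.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def write_seg(
    segments: pd.DataFrame, path: str | Path, sample: str = "sample"
) -> None:
    """SEG export: 1-based inclusive coordinates."""
    out = pd.DataFrame(
        {
            "sample": sample,
            "chrom": segments["chrom"],
            "start": segments["start"].astype(int) + 1,
            "end": segments["end"].astype(int),
            "n_probes": segments["n_probes"].astype(int),
            "seg_mean": segments["seg_mean"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG file back to internal 0-based half-open segments."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return pd.DataFrame(
        {
            "chrom": table["chrom"],
            "start": table["start"].astype(int) - 1,
            "end": table["end"].astype(int),
            "n_probes": table["n_probes"].astype(int),
            "seg_mean": table["seg_mean"],
        }
    )


def write_bed(calls: pd.DataFrame, path: str | Path, sample: str = "sample") -> None:
    """BED export of non-neutral calls; state in the name field."""
    aberrant = calls[calls["state"] != 0]
    with open(path, "w") as fh:
        for row in aberrant.itertuples():
            name = f"{sample}_{'gain' if row.state > 0 else 'loss'}"
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{name}\t{int(row.state)}\n"
            )


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "n_probes", "seg_mean", "state"]
    calls[cols].to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_cohort(matrix: pd.DataFrame, labels: pd.Series, path: str | Path) -> None:
    """Cohort matrix TSV: sample id index, subtype column, marker columns."""
    out = matrix.copy()
    out.insert(0, "subtype", labels.reindex(matrix.index))
    out.to_csv(path, sep="\t", index=True, index_label="sample")


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    table = pd.read_csv(path, sep="\t", index_col="sample")
    labels = table.pop("subtype")
    return table, labels


def write_fish_counts(counts: dict[str, dict[int, int]], path: str | Path) -> None:
    """Per-locus cell counts, one row per locus, columns cn0..cn4, cn_gt4."""
    rows = []
    for locus, c in counts.items():
        rows.append(
            {
                "locus": locus,
                **{f"cn{k}": c.get(k, 0) for k in range(5)},
                "cn_gt4": c.get(5, 0),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fish_counts(path: str | Path) -> dict[str, dict[int, int]]:
    table = pd.read_csv(path, sep="\t")
    out = {}
    for row in table.itertuples():
        out[row.locus] = {
            **{k: int(getattr(row, f"cn{k}")) for k in range(5)},
            5: int(row.cn_gt4),
        }
    return out
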