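"""Genome-imbalance summaries of a call track.

An aberration is a maximal run of adjacent same-state non-neutral
segments within a chromosome. Sizes are the bp extent of the run (the
segment spans already partition each chromosome at inter-probe
midpoints), and percentages are taken against the total length of
non-excluded chromosomes. The X chromosome is excluded by default: with a
sex-mismatched pooled reference, X log ratios reflect the sex difference
rather than somatic change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomeModel

DEFAULT_EXCLUDE = frozenset({"X"})


@dataclass
class ImbalanceSummary:
    n_gains: int
    n_losses: int
    mb_gained: float
    mb_lost: float
    pct_gained: float
    pct_lost: float
    excluded: frozenset[str] = field(default_factory=lambda: DEFAULT_EXCLUDE)

    @property
    def n_aberrations(self) -> int:
        return self.n_gains + self.n_losses

    @property
    def pct_changed(self) -> float:
        return self.pct_gained + self.pct_lost

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_gains": [self.n_gains],
                "n_losses": [self.n_losses],
                "n_aberrations": [self.n_aberrations],
                "mb_gained": [self.mb_gained],
                "mb_lost": [self.mb_lost],
                "pct_gained": [self.pct_gained],
                "pct_lost": [self.pct_lost],
                "pct_changed": [self.pct_changed],
                "excluded": [",".join(sorted(self.excluded))],
            }
        )


def aberration_size_table(
    calls: pd.DataFrame, exclude: frozenset[str] = frozenset()
) -> pd.DataFrame:
    """Merge same-state runs into aberrations; one row each, sorted by size.

    Expects a call track (chrom, start, end, state) whose segments are
    contiguous within each chromosome. Neutral segments break runs.
    """
    runs = []
    for chrom, group in calls.groupby("chrom", sort=False):
        if chrom in exclude:
            continue
        group = group.sort_values("start")
        current = None
        for row in group.itertuples():
            if row.state == 0:
                current = None
                continue
            if current is not None and current["state"] == row.state and current["end"] == row.start:
                current["end"] = row.end
            else:
                current = {"chrom": chrom, "start": row.start, "end": row.end,
                           "state": row.state}
                runs.append(current)
    table = pd.DataFrame(runs, columns=["chrom", "start", "end", "state"])
    table["size_bp"] = table["end"] - table["start"]
    return table.sort_values("size_bp", ignore_index=True)


def summarize_imbalance(
    calls: pd.DataFrame,
    genome: GenomeModel,
    exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
) -> ImbalanceSummary:
    """Counts, megabases and percent genome gained/lost/changed."""
    exclude = frozenset(exclude)
    unknown = set(calls["chrom"]) - set(genome.names)
    if unknown:
        raise ValueError(f"call track names unknown chromosomes: {sorted(unknown)}")
    denom = genome.total_length(exclude)  # raises if everything is excluded
    table = aberration_size_table(calls, exclude=exclude)
    gains = table[table["state"] == 1]
    losses = table[table["state"] == -1]
    bp_gained = int(gains["size_bp"].sum())
    bp_lost = int(losses["size_bp"].sum())
    return ImbalanceSummary(
        n_gains=len(gains),
        n_losses=len(losses),
        mb_gained=bp_gained / 1e6,
        mb_lost=bp_lost / 1e6,
        pct_gained=100.0 * bp_gained / denom,
        pct_lost=100.0 * bp_lost / denom,
        excluded=exclude,
    )
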