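"""FISH copy-number enumeration and concordance with array calls.

Per-locus cell counts over the copy-number categories {0, 1, 2, 3, 4, >4}
reduce to a modal copy number (with at least 50 cells scored, the usual
cytogenetic minimum), which maps to a three-state gain/loss/neutral
reading against a baseline ploidy of 2. Concordance compares that reading
with the dichotomized array call of the segment containing the locus
midpoint — BAC inserts (~100-200 kb) are far smaller than typical
segments, so the midpoint suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .simulate import FISH_CATEGORIES

MIN_CELLS = 50


@dataclass(frozen=True)
class FISHLocusResult:
    """Cell counts for one locus; categories 0..5 with 5 meaning ">4"."""

    locus: str
    counts: dict[int, int]
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(FISH_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown copy categories {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative cell count")

    @property
    def n_cells(self) -> int:
        return sum(self.counts.values())


def load_fish_loci() -> pd.DataFrame:
    """Packaged CanFam2 coordinates of the 20 cancer-gene BAC loci."""
    with resources.files("oacgh.data").joinpath("fish_loci_canfam2.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def modal_copy(result: FISHLocusResult, min_cells: int = MIN_CELLS) -> int:
    """Category with the maximal count; ties break toward 2, then lower.

    Raises when fewer than ``min_cells`` cells were scored (the 50-cell
    scoring rule).
    """
    if result.n_cells < min_cells:
        raise ValueError(
            f"locus {result.locus!r}: {result.n_cells} cells scored; "
            f"at least {min_cells} required"
        )
    best = max(result.counts.values())
    tied = [c for c, n in result.counts.items() if n == best]
    tied.sort(key=lambda c: (abs(c - 2), c))
    return tied[0]


def fish_state(modal: int, baseline_ploidy: int = 2) -> int:
    """Map a modal copy category to {-1, 0, +1} against the baseline."""
    if baseline_ploidy < 1:
        raise ValueError("baseline ploidy must be >= 1")
    if modal > baseline_ploidy:
        return 1
    if modal < baseline_ploidy:
        return -1
    return 0


def _array_state_at(calls: pd.DataFrame, chrom: str, pos: float) -> int:
    on = calls[(calls["chrom"] == chrom) & (calls["start"] <= pos) & (pos < calls["end"])]
    if len(on) == 0:
        raise ValueError(f"locus midpoint {chrom}:{int(pos)} outside the call track")
    return int(on.iloc[0]["state"])


def concordance_table(
    fish_results: list[FISHLocusResult],
    calls: pd.DataFrame,
    loci: pd.DataFrame | None = None,
    baseline_ploidy: int = 2,
    min_cells: int = MIN_CELLS,
) -> tuple[pd.DataFrame, float]:
    """Score each locus's FISH-implied state against the array call.

    ``loci`` supplies (locus, chrom, start, end) coordinates when the
    results themselves carry none (e.g. counts read from a bare TSV).
    Returns the per-locus record table and the fraction concordant.
    """
    coord = {}
    if loci is not None:
        coord = {
            row.locus: (row.chrom, row.start, row.end) for row in loci.itertuples()
        }
    records = []
    for res in fish_results:
        if res.chrom is not None:
            chrom, start, end = res.chrom, res.start, res.end
        elif res.locus in coord:
            chrom, start, end = coord[res.locus]
        else:
            raise ValueError(f"no coordinates for locus {res.locus!r}")
        modal = modal_copy(res, min_cells=min_cells)
        implied = fish_state(modal, baseline_ploidy)
        array = _array_state_at(calls, chrom, (start + end) / 2)
        records.append(
            {
                "locus": res.locus,
                "chrom": chrom,
                "modal_copy": modal,
                "fish_state": implied,
                "array_state": array,
                "concordant": implied == array,
            }
        )
    table = pd.DataFrame(records)
    fraction = float(table["concordant"].mean()) if len(table) else float("nan")
    return table, fraction
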