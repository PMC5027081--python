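"""Synthetic two-color aCGH data with planted truth.

Every input the pipeline consumes can be generated here: a probe grid on a
canine-like genome, two-color fluorescent signal pairs whose log2 ratios
carry planted copy-number aberrations (CNAs), subtype-labeled reference
cohorts of segmented marker values, per-locus FISH cell counts, and log2
expression matrices with planted high-variance rows. Each generator emits a
machine-readable truth record so downstream recovery can be scored.

The signal model is constructed to be exactly invertible by the
normalization stage: the green (reference) channel is lognormal around a
baseline intensity and the red (test) channel is ``green * 2**(shift +
noise)``, so ``log2(red/green)`` equals the planted shift plus Gaussian
noise — exactly the planted shift when ``noise_sd == 0``.

Reproducibility: one global seed fans out to fixed per-component
substreams, so e.g. the cohort can be regenerated without replaying the
probe-level simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel, chrom_sort_key

PROBE_LENGTH = 60  # oligo length in bp (60-mer array)
DEFAULT_SPACING = 13_000  # ~13 kb probe spacing
FISH_CATEGORIES = (0, 1, 2, 3, 4, 5)  # 5 encodes ">4"

SUBTYPE_LABELS = ("AML", "T-CLL", "B-CLL", "ALL", "B-LSA", "T-LSA", "HM")

_COMPONENT_STREAMS = {
    "genome": 0,
    "probes": 1,
    "profile": 2,
    "cohort": 3,
    "fish": 4,
    "expression": 5,
}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Independent substream for a named component of the simulation."""
    try:
        idx = _COMPONENT_STREAMS[component]
    except KeyError:
        raise ValueError(f"unknown component {component!r}") from None
    return np.random.default_rng(np.random.SeedSequence((int(seed), idx)))


@dataclass(frozen=True)
class PlantedCNA:
    """A planted aberration: half-open bp interval with a signed log2 shift."""

    chrom: str
    start: int
    end: int
    state: str  # "gain" | "loss"
    shift: float  # signed log2 shift; > 0 for gain, < 0 for loss

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.state not in ("gain", "loss"):
            raise ValueError(f"state must be 'gain' or 'loss', got {self.state!r}")
        if self.state == "gain" and self.shift <= 0:
            raise ValueError("gain requires a positive shift")
        if self.state == "loss" and self.shift >= 0:
            raise ValueError("loss requires a negative shift")


@dataclass(frozen=True)
class SubtypeSignature:
    """A tumor subtype: CNA templates with per-tumor occurrence frequencies."""

    label: str
    templates: tuple[tuple[PlantedCNA, float], ...]

    def __post_init__(self) -> None:
        if self.label not in SUBTYPE_LABELS:
            raise ValueError(f"unknown subtype label {self.label!r}")
        for _, freq in self.templates:
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"frequency {freq} outside [0, 1]")


@dataclass(frozen=True)
class FISHTruth:
    """True copy number at a locus and per-cell scoring concordance."""

    locus: str
    copy_number: int  # category in {0,1,2,3,4,5}; 5 means ">4"
    concordance: float  # probability a scored cell shows the true category

    def __post_init__(self) -> None:
        if self.copy_number not in FISH_CATEGORIES:
            raise ValueError(f"copy number {self.copy_number} outside 0..5")
        if not 0.0 < self.concordance <= 1.0:
            raise ValueError("concordance probability must be in (0, 1]")


def gen_probes(genome: GenomeModel, spacing: int = DEFAULT_SPACING) -> pd.DataFrame:
    """Lay probes at fixed spacing along each chromosome.

    Each chromosome gets ``floor(length / spacing)`` probes (at least one),
    at starts ``0, spacing, 2*spacing, ...``, sorted by (chromosome order,
    start). Columns: probe_id, chrom, start, end.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    frames = []
    for chrom in genome.names:
        length = genome.lengths[chrom]
        n = max(1, length // spacing)
        starts = np.arange(n, dtype=np.int64) * spacing
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"cfa{chrom}_{k}" for k in range(n)],
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + PROBE_LENGTH, length),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _check_non_overlapping(cnas: list[PlantedCNA]) -> None:
    by_chrom: dict[str, list[PlantedCNA]] = {}
    for cna in cnas:
        by_chrom.setdefault(cna.chrom, []).append(cna)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda c: c.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping planted CNAs on chromosome {chrom}: "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )


def planted_shifts(probes: pd.DataFrame, cnas: list[PlantedCNA]) -> np.ndarray:
    """Per-probe true log2 shift (0 outside every planted CNA)."""
    shifts = np.zeros(len(probes), dtype=float)
    chrom = probes["chrom"].to_numpy()
    start = probes["start"].to_numpy()
    for cna in cnas:
        inside = (chrom == cna.chrom) & (start >= cna.start) & (start < cna.end)
        shifts[inside] = cna.shift
    return shifts


def gen_signal_profile(
    probes: pd.DataFrame,
    cnas: list[PlantedCNA],
    noise_sd: float = 0.1,
    baseline_signal: float = 1000.0,
    green_log_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach two-color signals carrying the planted CNAs to a probe grid.

    For probes inside a planted interval the expected log2(red/green) is the
    planted shift; elsewhere it is 0. Both channels are strictly positive.

    Parameters
    ----------
    noise_sd:
        SD of the Gaussian noise added to the log2 ratio, in log2 units.
    baseline_signal:
        Median green-channel intensity (arbitrary fluorescence units).
    green_log_sd:
        Spread of the lognormal green channel (natural-log scale); affects
        per-channel brightness only, never the ratio.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if baseline_signal <= 0:
        raise ValueError("baseline_signal must be positive")
    _check_non_overlapping(cnas)
    rng = component_rng(seed, "profile")
    shifts = planted_shifts(probes, cnas)
    green = baseline_signal * np.exp(rng.normal(0.0, green_log_sd, len(probes)))
    log_ratio = shifts + (
        rng.normal(0.0, noise_sd, len(probes)) if noise_sd > 0 else 0.0
    )
    out = probes.copy()
    out["r_signal"] = green * np.exp2(log_ratio)
    out["g_signal"] = green
    return out


def truth_sidecar(cnas: list[PlantedCNA]) -> pd.DataFrame:
    """Planted CNAs as a table, sufficient to score downstream recovery."""
    rows = sorted(cnas, key=lambda c: (chrom_sort_key(c.chrom), c.start))
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in rows],
            "start": [c.start for c in rows],
            "end": [c.end for c in rows],
            "state": [c.state for c in rows],
            "shift": [c.shift for c in rows],
        }
    )


# ---------------------------------------------------------------------------
# Subtype cohorts
# ---------------------------------------------------------------------------

def _frac(chrom: str, lo: float, hi: float, genome: GenomeModel,
          state: str, shift: float) -> PlantedCNA:
    length = genome.lengths[chrom]
    return PlantedCNA(chrom, int(lo * length), int(hi * length), state, shift)


def default_signatures(genome: GenomeModel) -> list[SubtypeSignature]:
    """Default 7-subtype signature set on a 38+X canine-like genome.

    Lymphoma, leukemia and histiocytic subtypes are given recurrent-lesion
    templates in the regions reported for canine round cell tumors — CDKN2A-
    region loss on CFA 11 with CFA 22 proximal loss and CFA 29 gain for
    T-cell lymphoma, CFA 13 gain with CFA 14 / proximal CFA 3 loss for
    B-cell lymphoma, distal CFA 1 loss with CFA 12/25 gain and CFA 35 loss
    for acute lymphoblastic leukemia, and broad multi-chromosome loss plus
    CFA 13 gain for histiocytic malignancy — with invented signatures for the
    three leukemia subtypes the literature does not pin down. Frequencies
    are per-tumor occurrence rates chosen so a sampled tumor is identifiable;
    they are illustrative, not population estimates.
    """
    gain, loss = 0.58, -1.0
    mk = lambda c, lo, hi, st, sh: _frac(c, lo, hi, genome, st, sh)
    return [
        SubtypeSignature("AML", (
            (mk("2", 0.0, 1.0, "gain", gain), 0.85),
            (mk("6", 0.0, 1.0, "loss", loss), 0.75),
            (mk("19", 0.0, 1.0, "gain", gain), 0.70),
        )),
        SubtypeSignature("T-CLL", (
            (mk("5", 0.0, 1.0, "loss", loss), 0.85),
            (mk("7", 0.0, 1.0, "gain", gain), 0.75),
            (mk("21", 0.0, 1.0, "loss", loss), 0.70),
        )),
        SubtypeSignature("B-CLL", (
            (mk("4", 0.0, 1.0, "gain", gain), 0.85),
            (mk("9", 0.0, 1.0, "loss", loss), 0.75),
            (mk("24", 0.0, 1.0, "gain", gain), 0.70),
        )),
        SubtypeSignature("ALL", (
            (mk("1", 0.6, 1.0, "loss", loss), 0.85),
            (mk("12", 0.0, 1.0, "gain", gain), 0.75),
            (mk("25", 0.0, 1.0, "gain", gain), 0.70),
            (mk("35", 0.0, 1.0, "loss", loss), 0.60),
        )),
        SubtypeSignature("B-LSA", (
            (mk("13", 0.0, 1.0, "gain", gain), 0.90),
            (mk("14", 0.0, 1.0, "loss", loss), 0.70),
            (mk("3", 0.0, 0.5, "loss", loss), 0.60),
        )),
        SubtypeSignature("T-LSA", (
            (mk("11", 0.25, 0.45, "loss", loss), 0.90),  # CDKN2A region
            (mk("22", 0.0, 0.5, "loss", loss), 0.70),
            (mk("29", 0.0, 1.0, "gain", gain), 0.70),
        )),
        SubtypeSignature("HM", (
            (mk("16", 0.0, 1.0, "loss", loss), 0.90),
            (mk("31", 0.0, 1.0, "loss", loss), 0.80),
            (mk("12", 0.0, 1.0, "loss", loss), 0.60),
            (mk("14", 0.0, 1.0, "loss", loss), 0.60),
            (mk("36", 0.0, 1.0, "loss", loss), 0.60),
            (mk("13", 0.0, 1.0, "gain", gain), 0.60),
        )),
    ]


def _overlap_fractions(grid: pd.DataFrame, cna: PlantedCNA) -> np.ndarray:
    """Fraction of each grid bin covered by the CNA interval."""
    frac = np.zeros(len(grid), dtype=float)
    on = grid["chrom"].to_numpy() == cna.chrom
    lo = np.maximum(grid["start"].to_numpy(), cna.start)
    hi = np.minimum(grid["end"].to_numpy(), cna.end)
    width = (grid["end"] - grid["start"]).to_numpy()
    frac[on] = np.clip(hi - lo, 0, None)[on] / width[on]
    return frac


def gen_cohort(
    signatures: list[SubtypeSignature],
    n_per_subtype: int,
    marker_grid: pd.DataFrame,
    noise_sd: float = 0.15,
    seed: int = 0,
    id_prefix: str = "S",
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw a subtype-labeled cohort of segmented marker values.

    Each sample carries each of its subtype's CNA templates independently
    with the template's frequency (a Bernoulli draw); its marker value is
    the sum of carried shifts, overlap-weighted onto the marker grid, plus
    Gaussian noise.

    Returns ``(matrix, labels, carriers)``: samples x markers values, the
    per-sample subtype labels, and the Bernoulli truth table (one row per
    sample, one column per ``label:index`` template).
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 subtypes")
    if n_per_subtype < 2:
        raise ValueError("n_per_subtype must be >= 2")
    rng = component_rng(seed, "cohort")
    marker_names = [
        f"{c}:{s}-{e}"
        for c, s, e in zip(marker_grid["chrom"], marker_grid["start"], marker_grid["end"])
    ]
    rows, labels, carrier_rows = [], [], []
    template_cols = [
        f"{sig.label}:{i}" for sig in signatures for i in range(len(sig.templates))
    ]
    for sig in signatures:
        # precompute each template's footprint on the grid
        footprints = [_overlap_fractions(marker_grid, t) for t, _ in sig.templates]
        freqs = np.array([f for _, f in sig.templates])
        shifts = np.array([t.shift for t, _ in sig.templates])
        for k in range(n_per_subtype):
            carried = rng.random(len(freqs)) < freqs
            value = np.zeros(len(marker_grid))
            for j, footprint in enumerate(footprints):
                if carried[j]:
                    value += shifts[j] * footprint
            if noise_sd > 0:
                value += rng.normal(0.0, noise_sd, len(value))
            rows.append(value)
            labels.append(sig.label)
            carrier = dict.fromkeys(template_cols, 0)
            for j, c in enumerate(carried):
                carrier[f"{sig.label}:{j}"] = int(c)
            carrier_rows.append(carrier)
    ids = [f"{id_prefix}{i:03d}" for i in range(len(rows))]
    matrix = pd.DataFrame(rows, index=ids, columns=marker_names)
    return matrix, pd.Series(labels, index=ids, name="subtype"), pd.DataFrame(
        carrier_rows, index=ids
    )


# ---------------------------------------------------------------------------
# FISH counts and expression matrices
# ---------------------------------------------------------------------------

def gen_fish_counts(
    truth: FISHTruth, n_cells: int = 50, seed: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[int, int]:
    """Multinomial per-cell copy-number counts for one locus.

    The true category receives probability ``truth.concordance``; the
    remaining mass splits evenly between the two adjacent categories
    (entirely to the single neighbor at the ends of the 0..>4 scale).
    Counts sum to ``n_cells``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = component_rng(seed, "fish")
    probs = np.zeros(len(FISH_CATEGORIES))
    idx = FISH_CATEGORIES.index(truth.copy_number)
    probs[idx] = truth.concordance
    spill = 1.0 - truth.concordance
    neighbors = [i for i in (idx - 1, idx + 1) if 0 <= i < len(FISH_CATEGORIES)]
    for i in neighbors:
        probs[i] = spill / len(neighbors)
    counts = rng.multinomial(n_cells, probs)
    return {cat: int(c) for cat, c in zip(FISH_CATEGORIES, counts)}


def gen_expression(
    n_probes: int,
    groups: dict[str, int],
    effect_log2: float = 5.0,
    within_sd: float = 0.2,
    n_diff: int = 50,
    base_level: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Log2 expression matrix with planted differential rows.

    The first ``n_diff`` rows are shifted up by ``effect_log2`` in every
    group except the first (the first group acts as baseline); remaining
    rows sit at ``base_level`` with only within-group noise.

    Returns ``(matrix, roles, diff_mask)`` where ``roles`` maps each sample
    column to its group name and ``diff_mask`` flags planted rows.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(n < 1 for n in groups.values()):
        raise ValueError("every group needs at least 1 sample")
    if n_diff > n_probes:
        raise ValueError("n_diff cannot exceed n_probes")
    rng = component_rng(seed, "expression")
    group_names = list(groups)
    columns, roles = [], []
    for g in group_names:
        for k in range(groups[g]):
            columns.append(f"{g}_{k}")
            roles.append(g)
    diff_mask = np.zeros(n_probes, dtype=bool)
    diff_mask[:n_diff] = True
    data = np.full((n_probes, len(columns)), base_level)
    for j, g in enumerate(roles):
        if g != group_names[0]:
            data[diff_mask, j] += effect_log2
    data += rng.normal(0.0, within_sd, data.shape)
    matrix = pd.DataFrame(
        data, index=[f"probe_{i}" for i in range(n_probes)], columns=columns
    )
    return matrix, pd.Series(roles, index=columns, name="group"), diff_mask


def toy_cnas(genome: GenomeModel) -> list[PlantedCNA]:
    """Planted CNAs for the toy-genome smoke tests: two focal events, one
    whole-chromosome gain, and an X gain to exercise the exclusion rule."""
    return [
        PlantedCNA("1", 650_000, 1_950_000, "gain", 0.58),
        PlantedCNA("2", 1_300_000, 2_600_000, "loss", -1.0),
        PlantedCNA("3", 0, genome.lengths["3"], "gain", 0.58),
        PlantedCNA("X", 0, 650_000, "gain", 0.58),
    ]
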