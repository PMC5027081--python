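"""Genome models for the canine (CanFam2-like) karyotype.

The dog karyotype has 38 acrocentric autosome pairs plus the sex
chromosomes; copy-number work here uses the 38 autosomes and X, ordered
numerically with X last. Chromosome names are plain strings ("1".."38",
"X") and coordinates are 0-based half-open base pairs throughout the
package; file writers convert where a format demands otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Approximate CanFam2 autosome lengths in Mb, chromosome 1..38, followed by X.
# Largest autosome ~122 Mb, smallest ~24 Mb; total ~2.4 Gb.
_CANFAM2_MB = [
    122, 88, 92, 89, 89, 78, 81, 74, 61, 69,
    74, 72, 64, 61, 64, 60, 64, 56, 54, 58,
    51, 61, 55, 48, 51, 39, 46, 41, 42, 40,
    40, 39, 32, 42, 27, 31, 31, 24,
    127,  # X
]


def chrom_sort_key(name: str) -> tuple[int, int | str]:
    """Numeric-aware ordering: "1" < "2" < ... < "38" < "X"."""
    try:
        return (0, int(name))
    except ValueError:
        return (1, name)


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names with lengths in bp.

    Invariants: unique names, strictly positive lengths, autosomes before X.
    """

    names: tuple[str, ...]
    lengths: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        for name in self.names:
            if name not in self.lengths:
                raise ValueError(f"missing length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise ValueError(
                    f"chromosome {name!r} has nonpositive length {self.lengths[name]}"
                )
        if list(self.names) != sorted(self.names, key=chrom_sort_key):
            raise ValueError("chromosomes must be ordered numerically with X last")

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n != "X")

    def total_length(self, exclude: set[str] | frozenset[str] = frozenset()) -> int:
        """Summed length of non-excluded chromosomes in bp."""
        kept = [n for n in self.names if n not in exclude]
        if not kept:
            raise ValueError("every chromosome excluded; empty denominator")
        return sum(self.lengths[n] for n in kept)

    def order_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None


def gen_genome(
    n_autosomes: int = 38,
    length_scale: float = 1.0,
    include_x: bool = True,
    seed: int | None = None,
) -> GenomeModel:
    """Build a canine-like genome with ``n_autosomes`` autosomes (+ X).

    Lengths follow the CanFam2 profile (descending ~122 Mb to ~24 Mb),
    multiplied by ``length_scale``. The construction is deterministic;
    ``seed`` is accepted for interface uniformity but unused.

    Parameters
    ----------
    n_autosomes:
        Number of autosomes, at least 1. Beyond 38, the length profile
        cycles from the smallest value.
    length_scale:
        Multiplier applied to the default Mb lengths (e.g. ``1e-3`` gives
        a miniature genome for fast tests).
    """
    if n_autosomes < 1:
        raise ValueError("n_autosomes must be >= 1")
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    names = [str(i) for i in range(1, n_autosomes + 1)]
    mb = [_CANFAM2_MB[min(i, 37)] for i in range(n_autosomes)]
    if include_x:
        names.append("X")
        mb.append(_CANFAM2_MB[38])
    lengths = {
        n: max(1, int(round(m * 1_000_000 * length_scale))) for n, m in zip(names, mb)
    }
    return GenomeModel(names=tuple(names), lengths=lengths)


def canfam2_genome() -> GenomeModel:
    """The full-size default: 38 autosomes + X, ~2.4 Gb of autosome."""
    return gen_genome(38)


def toy_genome() -> GenomeModel:
    """Small preset for fast tests: 3 autosomes + X, ~1000 probes at 13 kb.

    350 + 300 + 250 autosomal probes plus 100 on X at the default spacing.
    """
    return GenomeModel(
        names=("1", "2", "3", "X"),
        lengths={"1": 4_550_000, "2": 3_900_000, "3": 3_250_000, "X": 1_300_000},
    )
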