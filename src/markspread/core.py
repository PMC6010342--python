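"""Core genomic containers shared across the package.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
Summits are absolute base positions, not offsets from peak starts.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths of a (possibly synthetic) genome."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval; the unit of profile orientation and
    nearest-gene assignment."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """5' end of the gene (last base for minus-strand genes)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Peak:
    """A ChIP enrichment interval with its point of maximal signal."""

    chrom: str
    start: int
    end: int
    summit: int
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.id!r}: start {self.start} >= end {self.end}"
            )
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.id!r}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start
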