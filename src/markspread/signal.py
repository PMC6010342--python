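"""Binned coverage tracks and ChIP z-score normalization.

The normalization chain is raw coverage -> log2(ChIP/control) -> genome-wide
z-score.  The z-score track is the signal unit used by all downstream
metaprofile and differential operations: it standardizes the log2 ratio of a
ChIP sample over its control (genomic input for a binding factor, an H3 ChIP
for a histone mark) to zero mean and unit SD over all genome bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import GenomeSpec

KINDS = ("raw", "log2ratio", "zscore")


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-bin signal vectors.

    ``data[chrom]`` has ``ceil(chrom_length / bin_size)`` entries; the last
    bin may cover fewer than ``bin_size`` bases.
    """

    genome: GenomeSpec
    bin_size: int
    data: dict[str, np.ndarray]
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if set(self.data) != set(self.genome.chrom_names):
            raise ValueError("track chromosomes do not match the genome")
        for chrom, vec in self.data.items():
            vec = np.asarray(vec, dtype=float)
            expect = self.genome.n_bins(chrom, self.bin_size)
            if vec.shape != (expect,):
                raise ValueError(
                    f"{chrom}: expected {expect} bins, got {vec.shape}"
                )
            self.data[chrom] = vec

    def same_geometry(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.genome.sizes == other.genome.sizes
        )

    def concat(self) -> np.ndarray:
        """All genome bins as one vector, in genome chromosome order."""
        return np.concatenate(
            [self.data[c] for c in self.genome.chrom_names]
        )

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            genome=self.genome,
            bin_size=self.bin_size,
            data={c: v.copy() for c, v in self.data.items()},
            kind=self.kind,
        )


def bin_coverage(
    per_base_values: Mapping[str, np.ndarray], bin_size: int
) -> BinnedTrack:
    """Average per-base values into fixed bins.

    Each bin is the mean of the bases it covers; a final partial bin is
    averaged over its actual width, so constant input stays constant.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    data: dict[str, np.ndarray] = {}
    lengths = []
    names = []
    for chrom, vals in per_base_values.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"chromosome {chrom!r} is empty")
        edges = np.arange(0, vals.size, bin_size)
        sums = np.add.reduceat(vals, edges)
        widths = np.diff(np.append(edges, vals.size))
        data[chrom] = sums / widths
        names.append(chrom)
        lengths.append(vals.size)
    genome = GenomeSpec(tuple(names), tuple(lengths))
    return BinnedTrack(genome=genome, bin_size=bin_size, data=data, kind="raw")


def log2_ratio(
    chip: BinnedTrack,
    control: BinnedTrack,
    pseudocount: float = 1.0,
    library_norm: bool = True,
) -> BinnedTrack:
    """Per-bin log2((chip + pc) / (control + pc)).

    With ``library_norm`` (default) the control is first rescaled so both
    tracks share the same genome-wide mean, removing the sequencing-depth
    confound before the ratio is taken.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not chip.same_geometry(control):
        raise ValueError("chip and control tracks have mismatched binning")
    scale = 1.0
    if library_norm:
        chip_mean = float(np.mean(chip.concat()))
        ctrl_mean = float(np.mean(control.concat()))
        if ctrl_mean <= 0:
            raise ValueError("control track has non-positive mean")
        scale = chip_mean / ctrl_mean
    data = {
        c: np.log2(
            (chip.data[c] + pseudocount)
            / (control.data[c] * scale + pseudocount)
        )
        for c in chip.genome.chrom_names
    }
    return BinnedTrack(
        genome=chip.genome, bin_size=chip.bin_size, data=data, kind="log2ratio"
    )


def zscore(track: BinnedTrack) -> BinnedTrack:
    """Standardize a log2-ratio track genome-wide to mean 0, SD 1.

    A single mean/SD over all genome bins is used (not per chromosome), so
    the output is one coherent z-score track.  Idempotent on an already
    standardized track.
    """
    if track.kind == "raw":
        raise ValueError("z-scoring expects a log2-ratio track, not raw counts")
    allbins = track.concat()
    if allbins.size < 2:
        raise ValueError("need at least 2 bins to standardize")
    mu = float(np.mean(allbins))
    sd = float(np.std(allbins))
    if sd == 0:
        raise ValueError("constant track: zero variance, cannot z-score")
    data = {
        c: (track.data[c] - mu) / sd for c in track.genome.chrom_names
    }
    return BinnedTrack(
        genome=track.genome, bin_size=track.bin_size, data=data, kind="zscore"
    )


def normalize_chip(
    chip: BinnedTrack,
    control: BinnedTrack,
    pseudocount: float = 1.0,
    library_norm: bool = True,
) -> BinnedTrack:
    """Convenience: raw chip + control -> z-score track in one call."""
    return zscore(log2_ratio(chip, control, pseudocount, library_norm))
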