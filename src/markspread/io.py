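"""Readers and writers for the text formats the pipeline touches.

BED and bedGraph are 0-based half-open throughout; peaks are BED6+1 with
an absolute 0-based summit coordinate in column 7.  All writers accept
optional '#'-prefixed header lines (used to embed the run seed and config
hash) which every reader skips, so write -> read round-trips are
identities.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import GeneModel, GenomeSpec, Peak
from .signal import BinnedTrack, bin_coverage

logger = logging.getLogger(__name__)


class BedFormatError(ValueError):
    pass


def read_chrom_sizes(path) -> GenomeSpec:
    names, lengths = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise BedFormatError(f"{path}:{ln}: expected 'name<TAB>length'")
        names.append(parts[0])
        lengths.append(int(parts[1]))
    return GenomeSpec(tuple(names), tuple(lengths))


def write_chrom_sizes(genome: GenomeSpec, path) -> None:
    lines = [
        f"{c}\t{l}" for c, l in zip(genome.chrom_names, genome.chrom_lengths)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _data_lines(path):
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        yield ln, line.rstrip("\n").split("\t")


def read_bed(path, kind: str = "peak"):
    """Read peaks (BED6+1, absolute summit in column 7) or genes (BED6).

    A peak line without a summit column falls back to the interval
    midpoint, with a logged warning.  Malformed lines raise with the line
    number.
    """
    if kind not in ("peak", "gene"):
        raise ValueError("kind must be 'peak' or 'gene'")
    items = []
    midpoint_fallbacks = 0
    for ln, parts in _data_lines(path):
        try:
            if len(parts) < 3:
                raise ValueError("fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            if kind == "gene":
                if len(parts) < 6:
                    raise ValueError("gene records need 6 columns (strand)")
                items.append(
                    GeneModel(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=parts[5],
                        id=name,
                    )
                )
            else:
                if len(parts) >= 7:
                    summit = int(parts[6])
                else:
                    summit = (start + end) // 2
                    midpoint_fallbacks += 1
                items.append(
                    Peak(
                        chrom=chrom, start=start, end=end, summit=summit, id=name
                    )
                )
        except ValueError as exc:
            raise BedFormatError(f"{path}:{ln}: {exc}") from exc
    if midpoint_fallbacks:
        logger.warning(
            "%s: %d peak(s) had no summit column; midpoints used",
            path,
            midpoint_fallbacks,
        )
    return items


def write_bed(items: Sequence, path, header: Sequence[str] = ()) -> None:
    lines = [f"# {h}" for h in header]
    for it in items:
        if isinstance(it, GeneModel):
            lines.append(
                f"{it.chrom}\t{it.start}\t{it.end}\t{it.id}\t0\t{it.strand}"
            )
        elif isinstance(it, Peak):
            lines.append(
                f"{it.chrom}\t{it.start}\t{it.end}\t{it.id}\t0\t.\t{it.summit}"
            )
        else:
            raise TypeError(f"cannot write {type(it).__name__} as BED")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedgraph(path, genome: GenomeSpec, bin_bp: int) -> BinnedTrack:
    """Read a bedGraph into a binned track.

    Values are rebinned by coverage-weighted mean; uncovered bases count
    as 0 (logged); overlapping records are an error.
    """
    per_base = {
        c: np.zeros(genome.length(c)) for c in genome.chrom_names
    }
    covered = {
        c: np.zeros(genome.length(c), dtype=bool) for c in genome.chrom_names
    }
    for ln, parts in _data_lines(path):
        if len(parts) < 4:
            raise BedFormatError(f"{path}:{ln}: expected 4 columns")
        chrom, start, end, value = (
            parts[0],
            int(parts[1]),
            int(parts[2]),
            float(parts[3]),
        )
        if chrom not in per_base:
            raise BedFormatError(f"{path}:{ln}: unknown chromosome {chrom!r}")
        if not 0 <= start < end <= genome.length(chrom):
            raise BedFormatError(f"{path}:{ln}: interval outside chromosome")
        if covered[chrom][start:end].any():
            raise BedFormatError(f"{path}:{ln}: overlapping intervals")
        covered[chrom][start:end] = True
        per_base[chrom][start:end] = value
    n_uncovered = sum(int((~c).sum()) for c in covered.values())
    if n_uncovered:
        logger.info(
            "%s: %d uncovered bases treated as 0", path, n_uncovered
        )
    track = bin_coverage(per_base, bin_bp)
    return BinnedTrack(
        genome=genome, bin_size=bin_bp, data=track.data, kind="raw"
    )


def write_bedgraph(
    track: BinnedTrack, path, header: Sequence[str] = ()
) -> None:
    """Write per-bin values, merging adjacent equal-value runs."""
    lines = [f"# {h}" for h in header]
    for chrom in track.genome.chrom_names:
        vals = track.data[chrom]
        L = track.genome.length(chrom)
        run_start = 0
        for i in range(1, vals.size + 1):
            if i == vals.size or vals[i] != vals[run_start]:
                s = run_start * track.bin_size
                e = min(i * track.bin_size, L)
                lines.append(f"{chrom}\t{s}\t{e}\t{vals[run_start]:.17g}")
                run_start = i
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns or "log2fc" not in df.columns:
        raise ValueError(
            f"{path}: expression table needs gene_id and log2fc columns"
        )
    return df


def write_expression(
    df: pd.DataFrame, path, header: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for h in header:
            fh.write(f"# {h}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class RunConfig:
    """Parameters of one pipeline run; hashed into output headers."""

    bin_bp: int = 50
    flank_bp: int = 3000
    bootstrap_fraction: float = 0.10
    bootstrap_reps: int = 1000
    alpha: float = 0.05
    pseudocount: float = 1.0
    control_type: str = "input"  # 'input' or 'h3'; never inferred from data
    min_run_bins: int = 3
    window_bins: int = 20
    min_abs_delta: float = 1.0
    merge_gap_bins: int = 5
    seed: int = 0
    out_dir: str = "."
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("bin_bp", "flank_bp", "bootstrap_reps", "window_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.control_type not in ("input", "h3"):
            raise ValueError("control_type must be 'input' or 'h3'")

    def config_hash(self) -> str:
        """Hash of the scientific parameters; file locations excluded so
        the same analysis in a different directory hashes identically."""
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("out_dir", "paths")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"seed={self.seed} config_hash={self.config_hash()}"]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
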