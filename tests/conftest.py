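from __future__ import annotations

import pytest

from markspread import BinnedTrack, GeneModel, GenomeSpec, Peak


@pytest.fixture
def small_genome() -> GenomeSpec:
    return GenomeSpec(("chr1", "chr2"), (300_000, 200_000))


def random_peaks(rng, genome, n, min_len=50, max_len=800, prefix="p"):
    peaks = []
    for i in range(n):
        chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
        L = genome.length(chrom)
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, L - length))
        summit = int(rng.integers(start, start + length))
        peaks.append(
            Peak(chrom=chrom, start=start, end=start + length,
                 summit=summit, id=f"{prefix}{i:04d}")
        )
    return peaks


def random_genes(rng, genome, n, min_len=500, max_len=3000, prefix="g"):
    genes = []
    for i in range(n):
        chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
        L = genome.length(chrom)
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, L - length))
        genes.append(
            GeneModel(chrom=chrom, start=start, end=start + length,
                      strand=str(rng.choice(["+", "-"])), id=f"{prefix}{i:04d}")
        )
    return genes


def random_track(rng, genome, bin_size, kind="log2ratio"):
    data = {
        c: rng.normal(size=genome.n_bins(c, bin_size))
        for c in genome.chrom_names
    }
    return BinnedTrack(genome=genome, bin_size=bin_size, data=data, kind=kind)
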