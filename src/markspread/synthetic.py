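"""Synthetic genomes, peaks, coverage tracks and expression tables.

The generator is a forward model of the germline chromatin scenario the
pipeline analyzes: a histone mark (think H3K4me3) peaks near gene 5' ends,
a reader protein ("binder") sits a fixed oriented distance from the mark
summit, and in the mutant genotype the mark spreads into the flanks of
every bound summit.  Expression fold-changes of the affected genes are
coupled to the per-gene spreading strength.  Every injected effect is
recorded so downstream stages can be tested against ground truth.

Coverage model
--------------
Per-bin counts are Poisson with rate ``background_rate * 2**s(x)`` where
``s(x)`` is the target log2 enrichment: a triangular kernel at each summit
plus, in the mutant, a flank elevation that starts at ``spread_onset_bp``
from the summit and decays linearly to zero over ``spread_extent_bp``.
Effect amplitudes are stated in z-units of the final normalized track; they
are converted to log2 units with the delta-method SD of the background
log2 ratio, ``sqrt(2/background_rate)/ln 2``, so that an injected amplitude
of 1.0 comes out near 1.0 on the z-score scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import GeneModel, GenomeSpec, Peak
from .signal import BinnedTrack

import pandas as pd


class PackingError(ValueError):
    """Requested genes cannot be placed without overlap."""


@dataclass
class PeakRecord:
    """Ground-truth record of the effects injected at one peak."""

    peak_id: str
    gene_id: str
    mark_summit: int
    binder_summit: int
    spread: bool
    amplitude_factor: float  # per-peak multiplier on spread_amplitude


@dataclass
class SyntheticTruth:
    """Forward-model parameters plus per-peak injection records.

    ``binder_summit_offset_bp`` is the oriented binder-minus-mark summit
    distance (negative = 5' of the mark along its gene).  Spreading is an
    elevation of ``spread_amplitude`` z-units beginning ``spread_onset_bp``
    from affected summits and decaying linearly over ``spread_extent_bp``.
    ``de_coupling_prob`` is the probability that a spread-affected gene is
    transcriptionally up-regulated.
    """

    binder_summit_offset_bp: int = -150
    spread_amplitude: float = 2.0
    spread_onset_bp: int = 500
    spread_extent_bp: int = 1500
    de_coupling_prob: float = 1.0
    de_effect_log2fc: float = 1.0
    records: list[PeakRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spread_onset_bp < 0:
            raise ValueError("spread_onset_bp must be >= 0")
        if self.spread_extent_bp <= 0:
            raise ValueError("spread_extent_bp must be positive")
        if not 0.0 <= self.de_coupling_prob <= 1.0:
            raise ValueError("de_coupling_prob must be in [0, 1]")

    @property
    def affected_genes(self) -> set[str]:
        return {r.gene_id for r in self.records if r.spread}


@dataclass
class SimulatedChIP:
    """One genotype's worth of simulated peak sets and coverage tracks."""

    genotype: str
    mark_peaks: list[Peak]
    binder_peaks: list[Peak]
    chip: BinnedTrack
    control: BinnedTrack
    binder_chip: BinnedTrack | None
    binder_control: BinnedTrack | None
    truth: SyntheticTruth


def log2_units_per_z(background_rate: float) -> float:
    """Delta-method SD (log2 units) of the background log2 ratio; the
    conversion factor from z-unit amplitudes to log2 enrichment."""
    return math.sqrt(2.0 / background_rate) / math.log(2.0)


def generate_genome(
    spec: GenomeSpec,
    n_genes: int,
    min_gene_len: int = 1000,
    max_gene_len: int = 3000,
    seed: int | None = None,
) -> list[GeneModel]:
    """Place non-overlapping stranded genes uniformly on the genome.

    Genes are allotted to chromosomes proportionally to length, gene
    lengths drawn uniformly in ``[min_gene_len, max_gene_len]``, and
    positions drawn by distributing the leftover space as random gaps.
    Raises :class:`PackingError` when the genes cannot fit.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 < min_gene_len <= max_gene_len:
        raise ValueError("invalid gene length bounds")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(spec.chrom_lengths, dtype=float)
    # proportional allotment, largest-remainder rounding
    quota = n_genes * lengths / lengths.sum()
    alloc = np.floor(quota).astype(int)
    rest = n_genes - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:rest]] += 1
    genes: list[GeneModel] = []
    counter = 0
    for chrom, L, g in zip(spec.chrom_names, spec.chrom_lengths, alloc):
        if g == 0:
            continue
        glens = rng.integers(min_gene_len, max_gene_len + 1, size=g)
        slack = L - int(glens.sum())
        if slack < 0:
            raise PackingError(
                f"{g} genes (total {int(glens.sum())} bp) do not fit on "
                f"{chrom} ({L} bp)"
            )
        gaps = np.sort(rng.integers(0, slack + 1, size=g))
        starts = gaps + np.concatenate(([0], np.cumsum(glens[:-1])))
        strands = rng.choice(["+", "-"], size=g)
        for s, l, st in zip(starts, glens, strands):
            genes.append(
                GeneModel(
                    chrom=chrom,
                    start=int(s),
                    end=int(s + l),
                    strand=str(st),
                    id=f"g{counter:05d}",
                )
            )
            counter += 1
    return genes


def _kernel_log2(
    nb: int, bin_size: int, summit: int, height_log2: float, width_bp: int
) -> np.ndarray:
    """Triangular log2-enrichment kernel evaluated at bin centers."""
    half = width_bp / 2.0
    lo = max(0, int((summit - half) // bin_size))
    hi = min(nb, int((summit + half) // bin_size) + 1)
    out = np.zeros(nb)
    centers = (np.arange(lo, hi) + 0.5) * bin_size
    out[lo:hi] = height_log2 * np.clip(1.0 - np.abs(centers - summit) / half, 0, None)
    return out


def _spread_log2(
    nb: int,
    bin_size: int,
    summit: int,
    amp_log2: float,
    onset_bp: int,
    extent_bp: int,
) -> np.ndarray:
    """Symmetric flank elevation: amp at |d|=onset decaying linearly to 0
    at |d|=onset+extent, evaluated at bin centers."""
    reach = onset_bp + extent_bp
    lo = max(0, int((summit - reach) // bin_size))
    hi = min(nb, int((summit + reach) // bin_size) + 1)
    out = np.zeros(nb)
    d = np.abs((np.arange(lo, hi) + 0.5) * bin_size - summit)
    frac = (d - onset_bp) / extent_bp
    out[lo:hi] = amp_log2 * np.where(
        (d >= onset_bp) & (d < reach), 1.0 - frac, 0.0
    )
    return out


def generate_peaks_and_tracks(
    genes: list[GeneModel],
    genome: GenomeSpec,
    n_peaks: int,
    truth: SyntheticTruth,
    genotype: str = "WT",
    bin_size: int = 50,
    enrich_height: float = 3.0,
    peak_width_bp: int = 800,
    noise_sd: float = 0.0,
    background_rate: float = 100.0,
    binder_width_bp: int = 600,
    binder_jitter_sd_bp: float = 25.0,
    anchor_window_bp: int = 500,
    with_binder: bool = True,
    seed: int | None = None,
) -> SimulatedChIP:
    """Simulate mark/binder peak sets and Poisson coverage tracks.

    Mark summits are anchored within ``anchor_window_bp`` of the 5' end of
    randomly chosen genes (strand-aware); binder summits sit
    ``truth.binder_summit_offset_bp`` from the mark summit along the gene
    orientation, with Gaussian jitter.  For ``genotype="MUT"`` every peak
    additionally receives the flank spreading elevation (scaled by a
    per-peak amplitude factor drawn uniformly in [0.5, 1.5]).  The random
    stream does not depend on genotype, so WT and MUT runs with equal
    seeds share peaks, records, and — when ``spread_amplitude`` is 0 —
    identical tracks.  ``noise_sd`` adds optional per-bin log-normal rate
    jitter (in z-units) on top of Poisson counting noise.
    """
    if genotype not in ("WT", "MUT"):
        raise ValueError("genotype must be 'WT' or 'MUT'")
    if peak_width_bp < bin_size:
        raise ValueError("peak_width_bp must be >= bin_size")
    if n_peaks > len(genes):
        raise ValueError(
            f"n_peaks={n_peaks} exceeds the {len(genes)} available gene anchors"
        )
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    rng = np.random.default_rng(seed)
    u = log2_units_per_z(background_rate)
    chosen = rng.choice(len(genes), size=n_peaks, replace=False)
    half = peak_width_bp // 2
    bhalf = binder_width_bp // 2
    records: list[PeakRecord] = []
    mark_peaks: list[Peak] = []
    binder_peaks: list[Peak] = []
    amp_factors = rng.uniform(0.5, 1.5, size=n_peaks)
    jitters = rng.normal(0.0, binder_jitter_sd_bp, size=n_peaks)
    anchors = rng.integers(0, anchor_window_bp + 1, size=n_peaks)
    for i, gi in enumerate(chosen):
        g = genes[gi]
        L = genome.length(g.chrom)
        sign = 1 if g.strand == "+" else -1
        s = g.tss + sign * int(anchors[i])
        s = int(np.clip(s, half + 1, L - half - 1))
        b = s + sign * (truth.binder_summit_offset_bp + int(round(jitters[i])))
        b = int(np.clip(b, bhalf + 1, L - bhalf - 1))
        pid = f"mark_{i:05d}"
        mark_peaks.append(
            Peak(chrom=g.chrom, start=s - half, end=s + half, summit=s, id=pid)
        )
        binder_peaks.append(
            Peak(
                chrom=g.chrom,
                start=b - bhalf,
                end=b + bhalf,
                summit=b,
                id=f"binder_{i:05d}",
            )
        )
        records.append(
            PeakRecord(
                peak_id=pid,
                gene_id=g.id,
                mark_summit=s,
                binder_summit=b,
                spread=True,
                amplitude_factor=float(amp_factors[i]),
            )
        )
    truth.records = records

    spread_on = genotype == "MUT" and truth.spread_amplitude != 0.0
    chip_d, ctrl_d, bchip_d, bctrl_d = {}, {}, {}, {}
    for chrom in genome.chrom_names:
        nb = genome.n_bins(chrom, bin_size)
        e_mark = np.zeros(nb)
        e_bind = np.zeros(nb)
        for rec, mp in zip(records, mark_peaks):
            if mp.chrom != chrom:
                continue
            e_mark += _kernel_log2(
                nb, bin_size, rec.mark_summit, enrich_height * u, peak_width_bp
            )
            if spread_on:
                e_mark += _spread_log2(
                    nb,
                    bin_size,
                    rec.mark_summit,
                    truth.spread_amplitude * rec.amplitude_factor * u,
                    truth.spread_onset_bp,
                    truth.spread_extent_bp,
                )
            if with_binder:
                e_bind += _kernel_log2(
                    nb,
                    bin_size,
                    rec.binder_summit,
                    enrich_height * u,
                    binder_width_bp,
                )
        if noise_sd > 0:
            e_mark = e_mark + rng.normal(0.0, noise_sd * u, size=nb)
        chip_d[chrom] = rng.poisson(background_rate * 2.0**e_mark).astype(float)
        ctrl_d[chrom] = rng.poisson(
            np.full(nb, background_rate)
        ).astype(float)
        if with_binder:
            bchip_d[chrom] = rng.poisson(
                background_rate * 2.0**e_bind
            ).astype(float)
            bctrl_d[chrom] = rng.poisson(
                np.full(nb, background_rate)
            ).astype(float)

    def _track(d):
        return BinnedTrack(genome=genome, bin_size=bin_size, data=d, kind="raw")

    return SimulatedChIP(
        genotype=genotype,
        mark_peaks=mark_peaks,
        binder_peaks=binder_peaks,
        chip=_track(chip_d),
        control=_track(ctrl_d),
        binder_chip=_track(bchip_d) if with_binder else None,
        binder_control=_track(bctrl_d) if with_binder else None,
        truth=truth,
    )


def generate_expression(
    genes: list[GeneModel],
    truth: SyntheticTruth,
    base_logfc_sd: float = 0.25,
    germline_fraction: float = 0.3,
    fdr: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a MUT/WT expression table coupled to the injected spreading.

    Unaffected genes draw log2 fold-changes from N(0, base_logfc_sd).  A
    spread-affected gene is up-regulated with probability
    ``truth.de_coupling_prob``; its effect size is
    ``de_effect_log2fc * amplitude_factor`` of its peak, tying expression
    increase to spreading strength.  The DE flag is a stand-in for an FDR
    cut: Benjamini-Hochberg on two-sided normal p-values computed against
    the known null SD.
    """
    from statsmodels.stats.multitest import multipletests
    from scipy.stats import norm as _norm

    gene_ids = [g.id for g in genes]
    known = set(gene_ids)
    bad = [r.gene_id for r in truth.records if r.gene_id not in known]
    if bad:
        raise ValueError(f"truth references unknown gene ids: {bad[:5]}")
    rng = np.random.default_rng(seed)
    factor = {
        r.gene_id: r.amplitude_factor for r in truth.records if r.spread
    }
    n = len(gene_ids)
    base = rng.normal(0.0, base_logfc_sd, size=n)
    coupled_draw = rng.random(n)
    germline = rng.random(n) < germline_fraction
    logfc = base.copy()
    affected = np.zeros(n, dtype=bool)
    for i, gid in enumerate(gene_ids):
        if gid in factor:
            affected[i] = True
            if coupled_draw[i] < truth.de_coupling_prob:
                logfc[i] = base[i] + truth.de_effect_log2fc * factor[gid]
    pvals = 2.0 * _norm.sf(np.abs(logfc) / base_logfc_sd)
    is_de = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": logfc,
            "is_de": is_de,
            "germline_specific": germline,
            "spread_affected": affected,
        }
    )
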