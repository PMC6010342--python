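"""Peak overlap detection, enrichment testing and closest-gene assignment.

Overlap follows the bedtools convention: two half-open intervals overlap
when they share at least ``min_overlap_bp`` bases (default 1).  Enrichment
and depletion of the overlap between two item lists is assessed with a
two-sided Fisher exact test over a stated universe, reported together with
the full 2x2 table and an explicit direction call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .core import GeneModel, GenomeSpec, Peak

logger = logging.getLogger(__name__)

MORE = "more_than_expected"
LESS = "less_than_expected"
NS = "ns"


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    n_a_overlapping: int
    fraction: float
    pairs: list[tuple[str, str]]


@dataclass
class EnrichmentResult:
    """2x2 Fisher test of two item lists against a universe.

    ``table`` is ((overlap, A only), (B only, neither)); counts sum to the
    universe size.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    direction: str
    expected_overlap: float
    n_universe: int
    alpha: float


@dataclass
class ShuffleNullResult:
    observed: int
    expected: float
    p_enrichment: float
    p_depletion: float
    n_perm: int


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str
    distance: int  # signed: negative when the summit lies 5' of gene.start
    strand: str


def _group_by_chrom(items) -> dict[str, list]:
    out: dict[str, list] = {}
    for it in items:
        out.setdefault(it.chrom, []).append(it)
    return out


def _overlapping_a_ids(
    a: Sequence[Peak], b: Sequence[Peak], min_overlap_bp: int
) -> tuple[set[str], list[tuple[str, str]]]:
    by_chrom_b = _group_by_chrom(b)
    trees = {
        chrom: IntervalTree.from_tuples(
            (p.start, p.end, p.id) for p in peaks
        )
        for chrom, peaks in by_chrom_b.items()
    }
    hit_ids: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for p in a:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(p.start, p.end)):
            if min(p.end, iv.end) - max(p.start, iv.begin) >= min_overlap_bp:
                hit_ids.add(p.id)
                pairs.append((p.id, iv.data))
    return hit_ids, pairs


def find_overlaps(
    a: Sequence[Peak], b: Sequence[Peak], min_overlap_bp: int = 1
) -> OverlapSummary:
    """Count peaks of A overlapping at least one peak of B.

    Each A peak is counted once however many partners it has; the pair list
    records every overlapping (a_id, b_id) pair.  The chromosome name sets
    of the two peak collections must agree, so that a fraction over A is
    meaningful.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    chroms_a = {p.chrom for p in a}
    chroms_b = {p.chrom for p in b}
    if a and b and chroms_a != chroms_b:
        raise ValueError(
            "peak sets cover different chromosomes: "
            f"{sorted(chroms_a ^ chroms_b)}"
        )
    hit_ids, pairs = _overlapping_a_ids(a, b, min_overlap_bp)
    n_a = len(a)
    n_hit = len(hit_ids)
    return OverlapSummary(
        n_a=n_a,
        n_b=len(b),
        n_a_overlapping=n_hit,
        fraction=(n_hit / n_a) if n_a else 0.0,
        pairs=pairs,
    )


def overlap_fraction(
    a: Sequence[Peak], b: Sequence[Peak], min_overlap_bp: int = 1
) -> float:
    """Percentage of A peaks overlapping B.  Asymmetric by definition."""
    if not a:
        raise ValueError("overlap_fraction: empty A peak set")
    return 100.0 * find_overlaps(a, b, min_overlap_bp).fraction


def fisher_two_sided(N: int, K: int, n: int, k):
    """Two-sided hypergeometric p: total probability of outcomes no more
    likely than the observed overlap ``k`` given margins ``K``, ``n`` in a
    universe of ``N``.  ``k`` may be a scalar or an array of observed
    counts (one pmf evaluation serves them all)."""
    lo, hi = max(0, K + n - N), min(K, n)
    karr = np.atleast_1d(np.asarray(k, dtype=int))
    if karr.size and not ((lo <= karr) & (karr <= hi)).all():
        raise ValueError("observed overlap inconsistent with the margins")
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = pmf[karr - lo]
    # tiny relative slack so exact probability ties are always included
    p = (pmf[None, :] * (pmf[None, :] <= p_obs[:, None] * (1 + 1e-13))).sum(
        axis=1
    )
    p = np.minimum(p, 1.0)
    return float(p[0]) if np.isscalar(k) or np.ndim(k) == 0 else p


def fisher_overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Fisher exact test for the overlap of two item lists.

    Direction is called against the hypergeometric expectation
    ``|A||B|/N``: more_than_expected / less_than_expected when the test is
    significant at ``alpha``, otherwise ns.
    """
    uni = set(universe)
    A, B = set(set_a), set(set_b)
    if len(uni) < 2:
        raise ValueError("universe must contain at least 2 items")
    if not A <= uni or not B <= uni:
        raise ValueError("set_a and set_b must be subsets of the universe")
    N, K, n = len(uni), len(A), len(B)
    k = len(A & B)
    p = fisher_two_sided(N, K, n, k)
    a, b_only = k, K - k
    c, d = n - k, N - K - n + k
    odds = (a * d) / (b_only * c) if b_only * c > 0 else float("inf")
    if a * d == 0 and b_only * c == 0:
        odds = float("nan")
    expected = K * n / N
    if p < alpha and k > expected:
        direction = MORE
    elif p < alpha and k < expected:
        direction = LESS
    else:
        direction = NS
    return EnrichmentResult(
        table=((a, b_only), (c, d)),
        odds_ratio=odds,
        p_value=p,
        direction=direction,
        expected_overlap=expected,
        n_universe=N,
        alpha=alpha,
    )


def _merged_intervals(peaks: Sequence[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, ps in _group_by_chrom(peaks).items():
        ivs = sorted((p.start, p.end) for p in ps)
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts), np.asarray(ends))
    return out


def _count_hits(starts, lengths, merged) -> int:
    """Number of [start, start+len) intervals intersecting the merged set."""
    ms, me = merged
    if ms.size == 0:
        return 0
    i0 = np.searchsorted(me, starts, side="right")
    ok = i0 < ms.size
    hit = np.zeros(starts.shape, dtype=bool)
    hit[ok] = ms[i0[ok]] < (starts + lengths)[ok]
    return int(hit.sum())


def shuffle_overlap_null(
    a: Sequence[Peak],
    b: Sequence[Peak],
    genome: GenomeSpec,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ShuffleNullResult:
    """Permutation null for the number of A peaks overlapping B.

    A peaks are re-placed uniformly at random within their own chromosome
    (length preserved) ``n_perm`` times.  Empirical p-values use the
    add-one rule (1 + exceedances) / (1 + n_perm), so the smallest
    attainable p is 1/(1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    merged = _merged_intervals(b)
    by_chrom = _group_by_chrom(a)
    for chrom, ps in by_chrom.items():
        L = genome.length(chrom)
        for p in ps:
            if len(p) > L:
                raise ValueError(f"peak {p.id!r} longer than {chrom}")
    observed = len(_overlapping_a_ids(a, b, 1)[0])
    counts = np.zeros(n_perm, dtype=int)
    empty = (np.array([]), np.array([]))
    for chrom, ps in by_chrom.items():
        L = genome.length(chrom)
        lens = np.array([len(p) for p in ps])
        mg = merged.get(chrom, empty)
        for i in range(n_perm):
            starts = rng.integers(0, L - lens + 1)
            counts[i] += _count_hits(starts, lens, mg)
    p_enr = (1 + int((counts >= observed).sum())) / (1 + n_perm)
    p_dep = (1 + int((counts <= observed).sum())) / (1 + n_perm)
    return ShuffleNullResult(
        observed=observed,
        expected=float(counts.mean()),
        p_enrichment=p_enr,
        p_depletion=p_dep,
        n_perm=n_perm,
    )


def assign_closest_gene(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    mode: str = "interval",
) -> dict[str, GeneAssignment]:
    """Assign every peak summit to its closest gene.

    Distance is the gap from the summit to the gene interval (0 when the
    summit falls inside the gene); ``mode="tss"`` measures to the gene 5'
    end instead.  Ties on distance are broken by the lexicographically
    smaller gene id, which makes the assignment deterministic; ties are
    logged.  The signed distance is negative when the summit lies before
    the gene start and positive when it lies past the gene end.
    """
    if mode not in ("interval", "tss"):
        raise ValueError("mode must be 'interval' or 'tss'")
    genes_by_chrom: dict[str, list[GeneModel]] = _group_by_chrom(genes)
    arrays = {}
    for chrom, gs in genes_by_chrom.items():
        gs = sorted(gs, key=lambda g: g.id)  # argmin then favors smaller id
        arrays[chrom] = (
            np.array([g.start for g in gs]),
            np.array([g.end for g in gs]),
            gs,
        )
    missing = [p.id for p in peaks if p.chrom not in arrays]
    if missing:
        raise ValueError(
            f"no genes on the chromosome of peaks: {missing}"
        )
    out: dict[str, GeneAssignment] = {}
    for p in peaks:
        starts, ends, gs = arrays[p.chrom]
        if mode == "interval":
            dist = np.maximum(
                np.maximum(starts - p.summit, p.summit - ends), 0
            )
        else:
            tss = np.where(
                np.array([g.strand for g in gs]) == "+", starts, ends - 1
            )
            dist = np.abs(p.summit - tss)
        j = int(np.argmin(dist))
        if int((dist == dist[j]).sum()) > 1:
            logger.info(
                "closest-gene tie for peak %s resolved to %s", p.id, gs[j].id
            )
        g = gs[j]
        if mode == "interval":
            if p.summit < g.start:
                signed = p.summit - g.start
            elif p.summit >= g.end:
                signed = p.summit - g.end
            else:
                signed = 0
        else:
            signed = p.summit - g.tss
        out[p.id] = GeneAssignment(
            gene_id=g.id, distance=int(signed), strand=g.strand
        )
    return out
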