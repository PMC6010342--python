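"""Independent brute-force oracles used to check the library.

Everything here is deliberately naive — plain Python loops, exact integer
arithmetic — and shares no code with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def brute_bin_means(values, bin_size):
    """Per-bin mean of a per-base vector, final partial bin included."""
    out = []
    for start in range(0, len(values), bin_size):
        chunk = values[start : start + bin_size]
        out.append(sum(chunk) / len(chunk))
    return out


def brute_overlap_pairs(a, b, min_overlap_bp=1):
    """All (a_id, b_id) pairs with >= min_overlap_bp shared bases."""
    pairs = set()
    for p in a:
        for q in b:
            if p.chrom != q.chrom:
                continue
            if min(p.end, q.end) - max(p.start, q.start) >= min_overlap_bp:
                pairs.add((p.id, q.id))
    return pairs


def brute_closest_gene(peaks, genes):
    """Exhaustive nearest-gene search; gap distance, lexicographic ties."""
    out = {}
    for p in peaks:
        best = None
        for g in genes:
            if g.chrom != p.chrom:
                continue
            gap = max(g.start - p.summit, p.summit - g.end, 0)
            key = (gap, g.id)
            if best is None or key < best[0]:
                best = (key, g)
        g = best[1]
        if p.summit < g.start:
            signed = p.summit - g.start
        elif p.summit >= g.end:
            signed = p.summit - g.end
        else:
            signed = 0
        out[p.id] = (g.id, signed, g.strand)
    return out


def exact_fisher_two_sided(N, K, n, k):
    """Two-sided Fisher p by exact integer enumeration of the
    hypergeometric distribution (no floating point until the end)."""
    lo, hi = max(0, K + n - N), min(K, n)
    weights = [math.comb(K, j) * math.comb(N - K, n - j) for j in range(lo, hi + 1)]
    wk = weights[k - lo]
    total = math.comb(N, n)
    return float(Fraction(sum(w for w in weights if w <= wk), total))


def brute_window_row(track_data, chrom_len, track_bin, summit, strand, flank, bin_bp):
    """Per-base window extraction for one summit; NaN off-chromosome."""
    bases = []
    for off in range(-flank, flank):
        p = summit + off
        if 0 <= p < chrom_len:
            bases.append(track_data[p // track_bin])
        else:
            bases.append(None)
    cols = []
    for j in range(0, len(bases), bin_bp):
        chunk = [v for v in bases[j : j + bin_bp] if v is not None]
        cols.append(sum(chunk) / len(chunk) if chunk else float("nan"))
    if strand == "-":
        cols = cols[::-1]
    return cols


def brute_sliding_regions(delta, window_bins, min_abs_delta, merge_gap_bins):
    """Brute-force sliding-window differential scan on one chromosome.

    Returns sorted (start_bin, end_bin, direction) tuples.
    """
    kept = {"up": [], "down": []}
    for i in range(len(delta) - window_bins + 1):
        m = sum(delta[i : i + window_bins]) / window_bins
        if m >= min_abs_delta:
            kept["up"].append((i, i + window_bins))
        if -m >= min_abs_delta:
            kept["down"].append((i, i + window_bins))
    regions = []
    for direction, wins in kept.items():
        merged = []
        for s, e in sorted(wins):
            if merged and s - merged[-1][1] <= merge_gap_bins:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        regions.extend((s, e, direction) for s, e in merged)
    return sorted(regions)


def simulate_subsample_mean_sd(rows, fraction, n_reps, rng):
    """Direct simulation of the subsample-mean SD, per column.

    An independent re-implementation of the resampling experiment: draw
    floor(fraction*n) rows without replacement n_reps times with its own
    RNG and return the SD of the replicate means per column.
    """
    rows = np.asarray(rows)
    n = rows.shape[0]
    m = int(np.floor(fraction * n))
    means = np.empty((n_reps, rows.shape[1]))
    for r in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        means[r] = rows[idx].mean(axis=0)
    return means.std(axis=0, ddof=1)
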