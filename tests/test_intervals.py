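import numpy as np
import pytest
from scipy.stats import fisher_exact

from markspread import (
    GeneModel,
    GenomeSpec,
    Peak,
    assign_closest_gene,
    find_overlaps,
    fisher_overlap_test,
    fisher_two_sided,
    overlap_fraction,
    shuffle_overlap_null,
)
from conftest import random_genes, random_peaks
from _oracles import brute_closest_gene, brute_overlap_pairs, exact_fisher_two_sided


def _peak(start, end, pid, chrom="chr1", summit=None):
    return Peak(chrom=chrom, start=start, end=end,
                summit=start if summit is None else summit, id=pid)


class TestFindOverlaps:
    def test_single_shared_base_counts(self):
        s = find_overlaps([_peak(0, 100, "a")], [_peak(99, 150, "b")])
        assert s.n_a_overlapping == 1 and s.pairs == [("a", "b")]

    def test_touching_halfopen_intervals_do_not_overlap(self):
        s = find_overlaps([_peak(0, 100, "a")], [_peak(100, 150, "b")])
        assert s.n_a_overlapping == 0 and s.pairs == []

    def test_min_overlap_threshold(self):
        a, b = [_peak(0, 100, "a")], [_peak(95, 150, "b")]
        assert find_overlaps(a, b, min_overlap_bp=5).n_a_overlapping == 1
        assert find_overlaps(a, b, min_overlap_bp=6).n_a_overlapping == 0

    def test_matches_bruteforce_and_is_symmetric(self, small_genome):
        rng = np.random.default_rng(10)
        for _ in range(50):
            a = random_peaks(rng, small_genome, 40, prefix="a")
            b = random_peaks(rng, small_genome, 40, prefix="b")
            got = set(find_overlaps(a, b).pairs)
            assert got == brute_overlap_pairs(a, b)
            flipped = {(y, x) for x, y in find_overlaps(b, a).pairs}
            assert got == flipped

    def test_each_a_peak_counted_once(self):
        a = [_peak(0, 1000, "a")]
        b = [_peak(i * 100, i * 100 + 50, f"b{i}") for i in range(5)]
        s = find_overlaps(a, b)
        assert s.n_a_overlapping == 1 and len(s.pairs) == 5

    def test_chromosome_mismatch_rejected(self):
        a = [_peak(0, 10, "a", chrom="chr1")]
        b = [_peak(0, 10, "b", chrom="chrX")]
        with pytest.raises(ValueError, match="chromosome"):
            find_overlaps(a, b)


class TestOverlapFraction:
    def test_three_of_four(self):
        a = [_peak(i * 1000, i * 1000 + 100, f"a{i}") for i in range(4)]
        b = [_peak(i * 1000 + 50, i * 1000 + 150, f"b{i}") for i in range(3)]
        b.append(_peak(3500, 3600, "b3"))
        assert overlap_fraction(a, b) == pytest.approx(75.0)

    def test_disjoint_sets_give_zero(self):
        a = [_peak(0, 100, "a")]
        b = [_peak(5000, 5100, "b")]
        assert overlap_fraction(a, b) == 0.0

    def test_asymmetric_by_definition(self):
        a = [_peak(0, 100, "a0"), _peak(200, 300, "a1")]
        b = [_peak(50, 80, "b0")]
        assert overlap_fraction(a, b) == pytest.approx(50.0)
        assert overlap_fraction(b, a) == pytest.approx(100.0)

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction([], [_peak(0, 10, "b")])


class TestFisherOverlapTest:
    def test_total_overlap_small_universe(self):
        # N=10, |A|=|B|=k=5: the most extreme table on both tails has
        # probability 1/252, so the two-sided p is 2/252.
        uni = [f"i{j}" for j in range(10)]
        res = fisher_overlap_test(uni[:5], uni[:5], uni)
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)
        assert res.direction == "more_than_expected"
        assert res.p_value == pytest.approx(
            exact_fisher_two_sided(10, 5, 5, 5), abs=1e-12
        )

    def test_observed_equals_expected_is_ns(self):
        # k=1 equals |A||B|/N = 100/100; OR exactly 1
        uni = [f"i{j}" for j in range(100)]
        res = fisher_overlap_test(uni[:10], uni[9:19], uni)
        assert res.table == ((1, 9), (9, 81))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.direction == "ns"

    def test_zero_overlap_large_expected_is_depleted(self):
        uni = [f"i{j}" for j in range(1000)]
        res = fisher_overlap_test(uni[:100], uni[100:200], uni)
        assert res.direction == "less_than_expected"
        assert res.p_value < 0.01

    def test_counts_sum_to_universe(self):
        uni = [f"i{j}" for j in range(57)]
        res = fisher_overlap_test(uni[:20], uni[10:35], uni)
        assert sum(sum(row) for row in res.table) == 57

    def test_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_overlap_test(["x"], ["a"], ["a", "b"])

    def test_random_tables_match_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            N = int(rng.integers(2, 80))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            table = [[k, K - k], [n - k, N - K - n + k]]
            expect = fisher_exact(table)[1]
            assert fisher_two_sided(N, K, n, k) == pytest.approx(
                expect, abs=1e-12
            )


class TestShuffleNull:
    def test_saturated_b_always_overlaps(self):
        genome = GenomeSpec(("chr1",), (10_000,))
        a = [_peak(i * 500, i * 500 + 100, f"a{i}") for i in range(10)]
        b = [_peak(0, 10_000, "b")]
        res = shuffle_overlap_null(a, b, genome, n_perm=100, seed=0)
        assert res.observed == 10
        assert res.expected == 10.0
        assert res.p_enrichment == 1.0  # every permutation ties the observed

    def test_deterministic_per_seed(self):
        genome = GenomeSpec(("chr1",), (50_000,))
        rng = np.random.default_rng(12)
        a = random_peaks(rng, GenomeSpec(("chr1",), (50_000,)), 20, prefix="a")
        b = random_peaks(rng, GenomeSpec(("chr1",), (50_000,)), 20, prefix="b")
        r1 = shuffle_overlap_null(a, b, genome, n_perm=150, seed=5)
        r2 = shuffle_overlap_null(a, b, genome, n_perm=150, seed=5)
        assert (r1.p_enrichment, r1.expected) == (r2.p_enrichment, r2.expected)

    def test_independent_placement_is_calibrated(self):
        # A placed independently of B: enrichment p should be roughly
        # uniform — conservative false-positive rate and central mean.
        genome = GenomeSpec(("chr1",), (100_000,))
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(200):
            a = random_peaks(rng, genome, 25, min_len=200, max_len=600, prefix="a")
            b = random_peaks(rng, genome, 25, min_len=200, max_len=600, prefix="b")
            res = shuffle_overlap_null(
                a, b, genome, n_perm=100, seed=int(rng.integers(2**31))
            )
            ps.append(res.p_enrichment)
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.10
        assert 0.40 < ps.mean() < 0.65

    def test_avoidance_flagged_as_depletion(self):
        genome = GenomeSpec(("chr1",), (20_000,))
        # B tiles the left half; A sits entirely on the right half
        b = [_peak(i * 500, i * 500 + 500, f"b{i}") for i in range(20)]
        a = [_peak(10_000 + i * 400, 10_300 + i * 400, f"a{i}") for i in range(20)]
        res = shuffle_overlap_null(a, b, genome, n_perm=200, seed=1)
        assert res.observed == 0
        assert res.expected > 5
        assert res.p_depletion < 0.05
        assert res.p_enrichment > 0.9

    def test_peak_longer_than_chromosome_rejected(self):
        genome = GenomeSpec(("chr1",), (100,))
        a = [Peak(chrom="chr1", start=0, end=100, summit=0, id="a")]
        ok = shuffle_overlap_null(a, a, genome, n_perm=100, seed=0)
        assert ok.observed == 1
        genome_small = GenomeSpec(("chr1",), (99,))
        with pytest.raises(ValueError, match="longer"):
            shuffle_overlap_null(a, a, genome_small, n_perm=100, seed=0)

    def test_too_few_permutations_rejected(self):
        genome = GenomeSpec(("chr1",), (1000,))
        a = [_peak(0, 10, "a")]
        with pytest.raises(ValueError, match="n_perm"):
            shuffle_overlap_null(a, a, genome, n_perm=10, seed=0)


class TestAssignClosestGene:
    def test_hand_case_nearer_gene_wins(self):
        genes = [
            GeneModel(chrom="chr1", start=1000, end=2000, strand="+", id="X"),
            GeneModel(chrom="chr1", start=0, end=100, strand="-", id="Y"),
        ]
        peak = _peak(400, 600, "p", summit=500)
        got = assign_closest_gene([peak], genes)["p"]
        assert got.gene_id == "Y"
        assert got.distance == 400
        assert got.strand == "-"

    def test_summit_inside_gene_distance_zero(self):
        genes = [GeneModel(chrom="chr1", start=100, end=300, strand="+", id="G")]
        got = assign_closest_gene([_peak(50, 400, "p", summit=200)], genes)["p"]
        assert got.distance == 0

    def test_upstream_summit_negative_distance(self):
        genes = [GeneModel(chrom="chr1", start=500, end=900, strand="+", id="G")]
        got = assign_closest_gene([_peak(100, 200, "p", summit=150)], genes)["p"]
        assert got.distance == -350

    def test_equidistant_tie_lexicographic(self):
        genes = [
            GeneModel(chrom="chr1", start=0, end=100, strand="+", id="gB"),
            GeneModel(chrom="chr1", start=300, end=400, strand="-", id="gA"),
        ]
        # summit 200: gap to gB is 100, gap to gA is 100 -> tie -> gA
        got = assign_closest_gene([_peak(150, 260, "p", summit=200)], genes)["p"]
        assert got.gene_id == "gA"

    def test_matches_exhaustive_search(self, small_genome):
        rng = np.random.default_rng(14)
        for _ in range(10):
            peaks = random_peaks(rng, small_genome, 50)
            genes = random_genes(rng, small_genome, 20)
            got = assign_closest_gene(peaks, genes)
            expect = brute_closest_gene(peaks, genes)
            for pid, a in got.items():
                assert (a.gene_id, a.distance, a.strand) == expect[pid]

    def test_translation_invariant(self, small_genome):
        rng = np.random.default_rng(15)
        peaks = random_peaks(rng, small_genome, 30)
        genes = random_genes(rng, small_genome, 15)
        shift = 7_919
        big = GenomeSpec(small_genome.chrom_names,
                         tuple(l + shift for l in small_genome.chrom_lengths))
        peaks2 = [Peak(chrom=p.chrom, start=p.start + shift, end=p.end + shift,
                       summit=p.summit + shift, id=p.id) for p in peaks]
        genes2 = [GeneModel(chrom=g.chrom, start=g.start + shift,
                            end=g.end + shift, strand=g.strand, id=g.id)
                  for g in genes]
        a1 = assign_closest_gene(peaks, genes)
        a2 = assign_closest_gene(peaks2, genes2)
        assert {p: a.gene_id for p, a in a1.items()} == {
            p: a.gene_id for p, a in a2.items()
        }

    def test_tss_mode_uses_five_prime_end(self):
        genes = [
            GeneModel(chrom="chr1", start=0, end=1000, strand="-", id="gMinus"),
            GeneModel(chrom="chr1", start=2000, end=3000, strand="+", id="gPlus"),
        ]
        # summit 1400: TSS of gMinus is 999 (gap 401), of gPlus 2000 (gap 600)
        got = assign_closest_gene([_peak(1300, 1500, "p", summit=1400)],
                                  genes, mode="tss")["p"]
        assert got.gene_id == "gMinus"
        assert got.distance == 401

    def test_chromosome_without_genes_rejected(self):
        genes = [GeneModel(chrom="chr1", start=0, end=10, strand="+", id="g")]
        peak = Peak(chrom="chr9", start=0, end=10, summit=5, id="lost")
        with pytest.raises(ValueError, match="lost"):
            assign_closest_gene([peak], genes)
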