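# Methods

`markspread` implements the genomic side of a chromatin "reader" study: a
protein binds a histone mark (the motivating system is a germline H3K4me3
reader in *C. elegans*), and in the mutant lacking the reader the mark
spreads into the flanks of the binding sites, with downstream consequences
for gene expression. The package provides the statistical machinery for
establishing each link in that chain from binned ChIP-seq coverage, and a
forward simulator with known ground truth so the whole chain can be
validated end to end.

## Signal model

Raw coverage is handled as fixed-bin tracks (default 50 bp). Normalization
follows the standard ChIP z-score construction:

1. library-size scaling — the control track is rescaled to the ChIP track's
   genome-wide mean, removing the sequencing-depth confound;
2. per-bin `log2((chip + c) / (control + c))` with pseudocount `c = 1`
   (count-scale data); the control is a configuration choice (`input` for a
   binding factor, an H3 ChIP for a histone mark), never inferred from data;
3. genome-wide standardization to mean 0, SD 1 — one mean/SD across all
   bins of all chromosomes, so the result is a single coherent z-score
   track. Standardizing per chromosome would let chromosome-level
   composition shift the scale of cross-genotype comparisons.

z-scoring is idempotent and affine-invariant; a constant track is an error
rather than a silent zero-division.

## Oriented metagene profiles

Each peak summit anchors a ±`flank_bp` window (default 3000) averaged into
`bin_bp` columns (default 50; 120 columns, summit at the boundary between
columns 59 and 60, columns labeled by their start offset). Values are read
per base from the track so the summit does not need to sit on a bin
boundary. Every summit is assigned to its closest gene, and rows of
minus-strand genes are reversed whole, so all rows read 5'→3' of the
associated gene. Windows crossing a chromosome end are masked (NaN) and
excluded from every mean's denominator — zero-filling would bias flank
means downward exactly where spreading is measured.

Two exact symmetries pin down the orientation arithmetic: flipping all gene
strands reverses the mean profile exactly, and additionally reflecting the
genome (base `p → L−1−p`, summit `s → L−s`) restores the original profile.
A spike at genomic offset +100 lands in column 62 for a plus-strand gene
and column 57 for a minus-strand gene at default geometry.

## Subsample-bootstrap confidence bands

The confidence band around a mean profile is built from subsample spread:
draw `floor(fraction · n)` summits (default fraction 0.10) without
replacement, record the per-bin mean, repeat `n_reps = 1000` times, and set
the band to `full-sample mean ± z_{1−α/2} · SD(replicate means)` with
normal quantiles (α = 0.05). Design choices that were genuinely open:

- **Without replacement** by default ("randomly selected" subsamples);
  `replace=True` is a documented switch.
- **One row draw shared across bins** per replicate, preserving the
  cross-bin correlation structure of the profile.
- **Centered on the full-sample mean**, not the replicate-mean average.

Because a 10% subsample mean is far noisier than the full-sample mean, the
band over-covers deliberately: for i.i.d. rows its half-width is
`z · sqrt(σ²/m · (n−m)/(n−1))`, about three times the full-sample standard
error at fraction 0.10. The test suite verifies the replicate-mean SD
against an independent simulation and the finite-population formula (both
to 5%), zero width for identical rows, and ≥95% empirical coverage.
Consequently the spreading test below is conservative.

## Spreading detection

Given bands for a reference and an alternative genotype on the same bin
geometry, a bin is called significant when the alternative's lower bound
exceeds the reference's upper bound (band separation). An onset on each side of the summit is the start
offset of the significant bin nearest the summit that begins a run of at
least `min_run_bins = 3` consecutive significant bins (150 bp at defaults);
the run requirement suppresses single-bin noise, encoding that spreading is
a sustained, not pointwise, divergence. `exclude_center_bp` can mask the
peak body; onsets are multiples of `bin_bp` labeled by bin start (so the
nearest upstream onset outside a 1000 bp exclusion is −1050, the bin
covering [−1050, −1000)).

## Overlap and enrichment statistics

Interval overlap uses half-open coordinates and the 1-bp rule (two peaks
overlap when they share ≥1 base; the threshold is configurable). Overlap
fractions are directional by definition (`100 · |A overlapping B| / |A|`).
List enrichment uses the two-sided Fisher exact test — implemented as the
total hypergeometric probability of outcomes no more likely than the one
observed — over an explicit universe, reported with the full 2×2 table and
a direction call (`more_than_expected` / `less_than_expected` / `ns`)
against the expectation `|A||B|/N`. For peak-level comparisons the peaks
are first mapped to genes and the test is run on a gene universe (all genes
or, when an expression table is supplied, the expressed genes); there is
no natural universe for raw peak sets, so the gene mapping is this
package's definition and is stated in the output. A
length-preserving permutation null (`shuffle_overlap_null`) provides an
interval-level alternative with add-one empirical p-values.

Closest-gene assignment measures the gap from the summit to the gene
interval (0 inside the gene; a TSS-distance mode is available), breaking
ties deterministically by lexicographic gene id and logging them. The
signed distance is negative 5' of the gene start.

## Differential regions and expression integration

The differential caller is intentionally simple plumbing: the sliding mean
of `alt − ref` over `window_bins` (default 20 bins = 1 kb) is thresholded
at `min_abs_delta` (default 1.0 z), and same-direction windows within
`merge_gap_bins` (default 5) are merged. It thresholds on effect size, not
on a count model — it is *not* a reimplementation of csaw-style
quasi-likelihood statistics, and is documented as such. With per-bin z
noise near 1 (the background-dominated case), a 20-bin window has null SD
≈ 0.32 z, so the 1.0 z default keeps the false-window rate near 10⁻³ per
window. Swapping the two tracks flips every region's direction and nothing
else.

Regions are assigned to closest genes, and per-gene mark change is the
**net integrated z difference** — the sum over the gene's regions of
`mean_delta × region width in bins`. The integrated form matters: a
region's mean delta is truncated by the calling threshold and saturates
near it regardless of the true effect size, whereas the integral grows
with both the height and the extent of the change. Gene lists are compared
with the Fisher machinery above, and mark change vs expression log2
fold-change is correlated with Spearman's rank correlation by default (the
scale linking z change to log2FC is unknown; Pearson is available).

## Synthetic data generator

The generator is a forward model of the study conditions, not a fixture:

- **Genes** are packed without overlap, uniformly via random gap
  allocation, lengths uniform in 1–3 kb, strands fair coin flips; an
  infeasible packing raises rather than truncating.
- **Coverage** is Poisson per bin: `counts ~ Poisson(λ · 2^s(x))` with
  background `λ = 100` per 50 bp bin and `s(x)` the target log2
  enrichment. Effect sizes are stated in z-units of the final normalized
  track and converted to log2 via the delta-method background SD
  `sqrt(2/λ)/ln 2` (≈0.204 log2 units per z at defaults). Because
  enriched bins inflate the genome-wide SD slightly, realized z
  elevations run a few percent below nominal; all recovery tests measure
  through the full pipeline, so this shrinkage is part of what they
  validate.
- **Mark peaks** are triangular kernels (height 3 z, width 800 bp) whose
  summits sit within 500 bp of the 5' end of randomly chosen genes,
  strand-aware — mirroring marks that localize around transcription start
  sites.
- **Binder peaks** sit `binder_summit_offset_bp` (default −150, i.e.
  150 bp 5') from the mark summit along the gene orientation, with 25 bp
  Gaussian jitter; binder coverage tracks are generated the same way.
- **Spreading** (mutant genotype only) elevates each affected summit's
  flanks by `spread_amplitude` z (default 2.0), starting at
  `spread_onset_bp` (500) from the summit and decaying linearly to zero
  over `spread_extent_bp` (1500), symmetric on both sides. Each peak
  carries an amplitude factor drawn uniformly in [0.5, 1.5], giving the
  between-gene effect-size variation that expression coupling needs.
- **Expression**: unaffected genes draw log2FC from N(0, 0.25);
  spread-affected genes are up-regulated with probability
  `de_coupling_prob` by `de_effect_log2fc × amplitude factor`, tying
  expression increase to spreading strength. The DE flag is a stand-in
  for an FDR cut: Benjamini–Hochberg at 5% on two-sided normal p-values
  against the known null SD. "Germline-specific" is an independent gene
  flag (default 30% of genes), not a cell-mixture model.

The random stream never depends on genotype, so equal seeds give identical
peak placements in both genotypes and bit-identical tracks when the
spreading amplitude is zero (the null generator is exactly
distribution-faithful). Everything is driven by one explicitly seeded
generator per operation; there is no hidden global state.

### What the generator does not emulate

Read-level artifacts (fragment-length effects, PCR duplicates,
mappability, GC bias), replicate structure, broad-vs-narrow peak shape
mixtures, chromatin-state heterogeneity across cell types, and any
germline/soma mixture. Passing tests therefore demonstrate that the
statistical machinery recovers known effects under a clean count model —
they do not certify performance on real libraries with those artifacts.

## Problem sizes used in validation

The test suite exercises onset recovery on 1000 summits over a 5 Mb
two-chromosome genome across 50 seeds (amplitude 1.0 z, the hardest
condition reported), the null false-positive rate on 200 seeds of a
null-amplitude generator (400 summits each), bootstrap fidelity on 2000
i.i.d. rows with 1000 replicates plus 200 coverage simulations, the
Fisher test against exact enumeration for every 2×2 table with N ≤ 60,
and the full mark→expression chain on 50 seeds (150 peaks, 400 genes).
These sizes give each stochastic criterion comfortable binomial margins
while keeping the default suite in the minutes range.

## Known limitations

- The differential caller has no replicate-aware error model; its regions
  are effect-size calls, suitable for joining to genes, not for FDR
  claims.
- Onset estimates are quantized to the profile bin (50 bp) and biased
  outward by up to one bin when the true onset falls mid-bin.
- The band-separation spreading criterion inherits the bootstrap band's
  conservativeness: real onsets are detected late rather than early, and
  weak spreading (≲0.4 z at the onset, at 1000 summits) is not called.
- `bedGraph` reading materializes per-base arrays per chromosome; fine for
  the megabase-scale genomes the package targets, not for mammalian-scale
  tracks (a bigWig path would be the natural extension).
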