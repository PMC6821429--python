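# Methods

## Library model and rationale

3′ tag scRNA-seq protocols anchor cDNA fragments at the poly(A) tail via
oligo-dT priming; fragments are typically ~200–300 bp and the sequenced
read (~100 nt) comes from the fragment end distal to the tail. A read's
3′-terminal aligned base therefore lies a stochastic, fragment-length-
dependent offset upstream of the cleavage (pA) site, and reads from a
common pA site pile up into a peak whose strand-aware 3′ edge approaches
the site. All inference in `apacell` is built on this geometry. Individual
cells are too shallow for per-site inference, so reads are pooled per
cell cluster (pseudobulk); clusters are an input, not computed here.

## Coordinates and regions

Coordinates are 0-based half-open internally; GTF (1-based inclusive) is
converted at the parsing boundary and BED is written natively half-open.
Per transcript, the 3′ UTR is taken from explicit `three_prime_utr`
features or derived as the exonic sequence downstream of the CDS end, and
then truncated to the transcript's last (3′-most) exon — truncation is
applied per transcript *before* per-gene merging, matching the
per-transcript nature of the rule. Per gene, transcript UTRs are merged
into maximal disjoint regions and numbered 5′→3′ in transcript
orientation (`<gene>:<k>`). Introns are per-transcript inter-exon gaps,
merged per gene and then *clipped* by (not discarded for) any overlap
with any gene's UTR region: dropping whole introns would delete genuine
intronic sequence far from any UTR, so clipping is the default and the
clip events are logged. Genes with contradictory strands or placed on
several chromosomes are skipped with a warning.

## Peak calling and splitting

The caller finds maximal strand-specific intervals of nonzero footprint
coverage (equivalent to a per-base coverage threshold of 1), merges
intervals separated by at most `max_gap` bases (default 0) and drops
intervals with fewer than `min_reads` members (default 5). This
contiguous-coverage formulation is used because every downstream step
depends only on intervals plus member reads. Peaks are assigned to UTR
regions first and remaining peaks to intronic regions, by same-strand
overlap of ≥ 1 nt without clipping (peaks genuinely extend into coding
sequence); a peak overlapping several regions goes to the larger overlap,
ties to the lexicographically lower region ID (logged).

Two adjacent pA sites closer than the fragment-length spread produce one
coverage peak. For every peak with ≥ `min_split_reads` members (default
20 — mixture fits on fewer points are unstable), a two-component 1-D
Gaussian mixture is fitted by EM to the member-read **3′-end** positions
(the quantity mechanistically tied to the pA site; fitting footprint
centers would blur the modes by half a read length). EM settings: means
initialized at the 25th/75th percentiles, equal weights, component
variances initialized at the sample variance, at most 500 iterations,
tolerance 1e-6, fixed seed. The peak is split iff the means are separated
by more than `sd_factor`·max(σ₁, σ₂) (default 3 — the conservative
reading of "three standard deviations of the fitted Gaussians") AND by at
least `min_separation` = 75 nt. The boundary is the coordinate between
the means where the weighted component densities are equal (bisection;
midpoint fallback if no crossing exists); members are partitioned by
position, sub-peaks span the min..max of their members, and splitting is
applied recursively so a peak covering three sites can resolve further.
Non-convergent or degenerate (σ < 1e-6) fits leave the peak unsplit.
Member multisets are conserved exactly across splits.

## Counting, CPM and filters

A read is counted to the peak containing its 3′ end; a read overlapping
peaks without containing its 3′ end in any (possible because split
sub-peaks span only member 3′ ends) is counted once to the 5′-most
overlapped peak. Each read is counted at most once. Whether reads
spanning two peaks should instead be counted fractionally is an open
choice; the 3′-end rule is this package's decision, stated here because
the original granularity is not specified upstream.

CPM uses per-cluster totals over the peak set being filtered; the UTR and
intronic sets are normalized independently, keeping the two filters
decoupled. UTR peaks are kept when their CPM total over clusters is
strictly greater than 10, then removed when the sense-strand genomic
sequence 10–140 nt downstream of the 3′ edge (1-based offsets, inclusive)
contains ≥ 8 consecutive As — the internal-priming signature. Intronic
peaks require a raw-count total ≥ 50 AND CPM total ≥ 10, with a stricter
A-run rule (≥ 7 As, 1–200 nt), because intronic peaks show far higher
internal-priming contamination. Count/CPM filtering precedes the A-run
scan, and the filter is idempotent (re-filtering its own output removes
nothing, since shrinking denominators only raise surviving CPMs). PAS
benchmarking scans the window from 30 nt upstream to 120 nt downstream of
each 3′ edge for AATAAA/ATTAAA on the sense strand.

## Statistics

Differential usage per multi-peak UTR: Pearson chi-squared test of
independence on the raw peaks × clusters count table, without Yates
correction (tables with any expected count < 1 are flagged but still
tested; no small-count rule is imposed). Zero-total columns are dropped;
tables left with fewer than two nonzero rows or two columns are
untestable and excluded from the BH correction, which runs across all
tested UTRs (q < 0.05 significant). PUI values are computed from raw
counts, not CPM, with pseudocount 1. Direction calls (shortened/
lengthened) are restricted to two-peak UTRs — the dominant class among
dynamic events — via the proximal PUI comparison for a designated cluster
pair; UTRs with more peaks get per-peak 2×K tests (each peak against the
sum of its siblings, BH within the UTR). The global direction excess uses
a one-tailed binomial test with p = P(X ≥ max(n_short, n_long)),
X ~ Bin(n, ½). Rank comparisons of PUI distributions are two-tailed by
default and one-tailed only when the caller pre-registers a direction;
both the significant-only and all-multi-peak subsets are available to the
caller, since either can be of interest. Intronic testing compares each
intronic peak's counts Ci to CU, the summed counts of the same gene's
3′ UTR peaks downstream of it in transcript orientation, as a 2×K
chi-squared with BH across intronic peaks. Per-cell analysis computes,
per cell, the mean proximal PUI over multi-peak UTRs covered by ≥ 1 read
in that cell (NaN when none qualifies). UTR expression sums peak counts
per UTR, converts to CPM and quantile-normalizes across clusters, with
ties averaged over ranks and the target distribution interpolated at
fractional ranks.

## Synthetic experiments

The generator emulates the library model with defaults chosen as the
study conditions: fragment length ~ Normal(250 nt, 50 nt) truncated to
[read length, 600 nt]; read length 100 nt; 60 genes (alternating strand)
with two pA sites 400 nt apart; two clusters ("naive", "activated") of
100 cells at ~1000 reads/cell (≈ 200k reads) with proximal usage
0.3/0.7 vs 0.7/0.3 — a strong, bidirectionally asymmetric shift of the
kind seen between resting and activated immune cells; 25% of genes carry
an intronic pA site (usage 0.1 vs 0.3); internal-priming rate 0.05 per
read. Each gene block has two exons; every pA site sits ≥ 600 nt (one
maximal fragment) inside its exon or intron, so simulated footprints
never span splice junctions and reads can be emitted as contiguous,
already-aligned SAM records (the pipeline's input contract starts at
aligned, deduplicated BAMs). A canonical PAS (AATAAA, C-flanked so no
filterable A-run can form against the background) ends 20 nt upstream of
every true site; a 30-base A-run decoy is planted 700 nt past the distal
site — far enough that decoy coverage cannot touch true-site coverage and
that true 3′-edge windows stay clean — and internal-priming reads arise
at it exactly like at a true site. Background sequence is uniform-random
with A/T homopolymer runs capped at 5, below both filter thresholds, so
by construction the only filterable A-runs are the decoys. One RNG stream
(config seed) drives all draws in documented order: cells per cluster,
per-read gene, per-gene site choice, fragment lengths; identical seeds
give byte-identical output files.

What the simulator does **not** model: sequencing errors, UMI collisions,
ambient RNA, doublets, expression heterogeneity between genes, multiple
overlapping genes, alternative splicing, or biological peak-shape
irregularities. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated library model, not
performance on the full messiness of real data.

## Problem sizes and numerical choices

Tests and the acceptance script use: 1000 random tables/p-vectors for
oracle equivalence; 1000 null UTRs (2 clusters × 500 reads) for type-I
control; 100 shifted UTRs for power; the default 60-gene / 200k-read
simulation for recovery, internal-priming and 20%-downsampling analyses;
40-gene / 100k-read simulations at spacings {100, 200, 300, 500} nt for
the resolution curve; and 200 + 200 synthetic bimodal/unimodal peaks for
split performance. These sizes give stable estimates (binomial SEs of a
few percent) at desk scale. Degenerate inputs are handled explicitly:
empty read sets yield empty peak lists; zero-total count columns are hard
errors naming the cluster; all-tied rank tests return p = 1; peaks with
constant member positions are never split.

## Known limitations

Resolution below ~150 nt site spacing is intrinsically limited by the
fragment-length spread (the 3-SD split rule cannot distinguish such
modes), mirroring the behaviour of the underlying method class. The
UTR-overlap subtraction for introns is strandless, which is conservative
for overlapping antisense genes. The alternative change-point peak caller
is reserved in the interface but intentionally not implemented.
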