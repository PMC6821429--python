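# apacell

Cell-type-specific analysis of **alternative polyadenylation (APA)** from
3′ tag scRNA-seq data (10x/Drop-seq-style libraries).

3′ tag protocols prime on the poly(A) tail, so aligned read 3′ ends pile up
just upstream of each polyadenylation (pA) site. Pooling the reads of all
cells in a cluster ("pseudobulk") turns each cluster into a deeply covered
3′-end library, from which `apacell`:

1. builds per-gene disjoint **3′ UTR regions** and UTR-free **intronic
   regions** from a GTF annotation;
2. calls strand-aware coverage **peaks**, assigns them to regions with
   proximal-first indices, and splits peaks covering two adjacent pA sites
   with a two-component **Gaussian mixture** (split when the modes are
   more than 3 fitted SDs and ≥ 75 nt apart);
3. counts reads per peak per cluster, normalizes to **CPM**, and removes
   low-usage peaks (total CPM ≤ 10) and **internal-priming** artifacts
   (≥ 8 consecutive genomic As 10–140 nt downstream of the 3′ edge;
   intronic peaks: ≥ 7 As in 1–200 nt, plus ≥ 50 reads and ≥ 10 CPM);
4. tests each multi-peak 3′ UTR for **differential pA-site usage** across
   clusters with a chi-squared test on raw counts and Benjamini–Hochberg
   FDR (q < 0.05), quantifying usage with the proximal polyA usage index

   ```
   proximal PUI = log2( (C1 + 1) / ⟨C + 1⟩ )
   ```

   where `C1` is the proximal-peak count and `⟨·⟩` the geometric mean over
   all the UTR's peaks — higher PUI in cluster A than B means 3′ UTR
   *shortening* in A. Global shortening/lengthening excess is assessed by a
   one-tailed binomial test, PUI distributions by Wilcoxon/Kruskal–Wallis,
   and intronic pA usage per intronic peak against the gene's downstream
   3′ UTR counts via `intronic PUI = log2((Ci+1)/(CU+1))`;
5. produces UTR-level **expression** (summed peak counts, CPM, quantile
   normalization) and per-cell mean proximal PUI for single-cell-level APA.

A fully synthetic-data generator (`apacell.simdata`) emulates the library
model — fragment lengths ~ Normal(250, 50), 100 nt reads, cluster-specific
site usage, planted PAS motifs, planted A-run decoys that attract
internal-priming reads — with complete per-gene and per-read ground truth,
so every stage is testable offline.

## Worked example

Simulate a 12-gene experiment (two clusters, *naive* and *activated*,
~200k reads) and run the full pipeline:

```bash
apacell simulate --outdir demo --n-genes 12 --seed 1
apacell all --bam demo/reads.sam --gtf demo/annotation.gtf \
    --fasta demo/genome.fa --clusters demo/clusters.tsv \
    --outdir demo_out --seed 1
```

The run manifest reports, among others:

```
"assignment":  {"n_utr_peaks": 24, "n_intron_peaks": 3, "n_unassigned": 0},
"splitting":   {"n_utr_splits": 12, "n_intron_splits": 0},
"filtering":   {"utr_kept": 24, "intron_kept": 3},
"statistics":  {"n_tested": 12, "n_significant": 12,
                "n_shortened_in_A": 12, "n_lengthened_in_A": 0,
                "binomial_p": 0.000244140625,
                "n_intronic_significant": 3}
```

Each of the 12 genes was simulated with proximal usage 0.7 in *activated*
vs 0.3 in *naive*; the 12 merged two-site peaks were all split, every
decoy peak was removed by the internal-priming filter, and all 12 UTRs are
called significantly *shortened in activated* (global one-tailed binomial
p = 2.4e-4 for 12/12 events). `demo_out/apa_tests.tsv` holds the per-UTR
statistics, e.g.:

```
utr_id   n_peaks  chi2     p    pui_activated  pui_naive  q    direction
G0001:1  2        1965.41  0.0  0.600          -0.614     0.0  shortened_in_activated
```

Other subcommands (`regions`, `peaks`, `count`, `test`, `report`) run
progressively longer prefixes of the same pipeline; every parameter can
come from a flat `key = value` config file (`--config`) with CLI flags
taking precedence.

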