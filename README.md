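# repseq

A toolkit for comparing B-cell receptor (BCR) repertoire sequencing
methods. It implements the full computational battery such comparisons
need: amplicon read preparation (quality, Ig-similarity, primer, length
filters and V/J germline gene assignment), BCR sequence-network clonality
metrics, IgHV gene-usage comparison statistics, amplicon-length trimming
experiments, RNA-vs-DNA repertoire overlap, and a closed-form model of how
sequencing depth limits the accuracy with which a clone's frequency can be
measured. A synthetic-repertoire generator emulates the sample types such
studies use — diverse healthy peripheral blood, and highly clonal CLL /
lymphoblastoid cell-line populations — including somatic-hypermutation
lineages, per-cell transcript variability for RNA input, nonproductive
second-allele rearrangements for genomic DNA input, and platform error
profiles (MiSeq-like substitutions at 2.06×10⁻⁴/base; a 454-like profile
with homopolymer indels).

It is written for immunologists and bioinformaticians designing or
benchmarking AIRR-seq experiments: how deep to sequence, what a shorter
amplicon costs in repertoire information, whether RNA or genomic DNA input
is preferable, and whether two protocols capture the same repertoire.

## The measures and models

**Sequence network.** Reads are deduplicated into vertices weighted by read
count; vertices at edit distance exactly 1 (one substitution or indel) are
joined by edges, and connected components are clusters, interpreted as
clonal lineages. Three clonality measures summarise a network:

- **vertex Gini index** — Gini unevenness of vertex read counts, G =
  Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄); 0 for a perfectly even (diverse) repertoire, →1 for
  a clonal one;
- **cluster Gini index** — the same measure over cluster sizes (read mass
  per cluster by default), reflecting lineage/mutational structure;
- **maximum cluster size** — percentage of all reads in the largest
  cluster, the degree of clonal expansion.

**Gene-usage comparison.** Per-sample IgHV frequency vectors are compared
by regression through the origin (slope = Σxy/Σx², R² = squared Pearson
correlation), optionally restricted to genes below a frequency threshold in
both samples (default 15%) where re-sampling stochasticity dominates.
Method differences per gene are tested with paired Wilcoxon and t-tests
under Bonferroni correction.

**Depth model.** For a clone at true proportion pᵢ sequenced to depth N,
the observed count is Binomial(N, p) with p = pᵢ − e·l (per-base error
rate e over length l; e defaults to 0). The probability of observing the
clone within ±10% of its expected count is

    P = Σ_{i=⌈0.9·N·pᵢ⌉}^{⌊1.1·N·pᵢ⌋} C(N,i) pⁱ (1−p)^{N−i}

and the probability of seeing a clone at all is the Poisson tail
1 − e^{−N·p}. The band sum is computed by an exactly-anchored term
recurrence accurate to ~1e-10 up to N = 10⁷.

## Worked example

```
$ repseq depth --p 0.0004 --n 1000000
0.957238
```

A clone at 0.04% of the repertoire is recovered within ±10% of its true
proportion with probability 0.957 at one million reads; at 100,000 reads
the same probability is only 0.523 (`repseq depth --p 0.0004 --n 100000`),
which is why rare-clone studies need deep sequencing, while a 4% clone is
already measured accurately (p ≥ 0.96) at 10,000 reads.

The end-to-end demonstration simulates one healthy and one CLL sample,
runs every comparison, and writes a tidy report plus a checksummed
manifest (byte-identical on re-runs with the same seed):

```
$ repseq demo --seed 42 --out demo_out
$ head demo_out/report.tsv
block   metric  value
sequencing_repeat       r_squared       0.99919
sequencing_repeat       slope   0.998887
sequencing_repeat_low_freq      r_squared       0.997859
...
```

The report shows the behaviour the method comparison is about:
re-sequencing the same amplified pool is nearly perfectly reproducible
(R² = 0.9992), independent re-amplification adds template re-sampling noise
(R² = 0.9982), differing platforms add capture bias on top (R² = 0.9932),
and every arm degrades further on the low-frequency (<15%) gene subset.
Paired gene tests between identical methods find 0 of 20 genes
significant. The synthetic CLL sample is strongly clonal (vertex Gini
0.886, largest cluster 84% of reads) while the healthy sample is diverse
(vertex Gini 0.270, largest cluster 0.5%), and every trimming window
(5'RACE-like 250 bp, CDR3-only, RNA-capture window) reduces the number of
unique sequences relative to full-length reads.

Other subcommands: `simulate`, `process`, `network`, `usage`, `compare`,
`trim-experiment`, `overlap`, `depth-curve` (see `repseq --help`).

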