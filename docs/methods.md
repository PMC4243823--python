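# Methods

## Scope and data model

The package reproduces the computational core of a BCR repertoire
method-comparison study on synthetic data. No public patient data exist
for this design, so a generator (`repseq.synthetic`) stands in for the
samples; every downstream module (read processing, networks, gene usage,
comparisons, depth model) is agnostic to where its input came from and
accepts real FASTQ/FASTA through the same interfaces.

Coordinates are 0-based half-open everywhere. All randomness flows from
integer seeds through `numpy.random.default_rng`; identical seeds give
byte-identical outputs, including the FASTQ/TSV artifacts and their
checksums.

## Synthetic repertoire generator

**Germline reference.** A toy library of independent random V (default
200 nt) and J (50 nt) segments. Pairwise V distances are verified ≥10
substitutions so that gene assignment on the toy reference is unambiguous
and call accuracy can be scored exactly against ground truth. Junction
anchors sit 10 nt from the V 3' end (end of FR3) and 10 nt into the J
(start of FR4); the CDR3 window of a simulated read is therefore
anchor-to-anchor. The toy reference deliberately omits real-world
complications — allelic variants, gene families with near-identical
members, truncated pseudogenes — so gene-call accuracy here is an upper
bound on real performance.

**Clone frequencies.** Each clone is a V + random N-region insert (6–18 nt)
+ J rearrangement. Sample types differ only in the clone-frequency profile:

- *healthy*: symmetric Dirichlet(α=10) across clones, capped at 5% by
  water-filling. The flat α was calibrated so that the downstream network
  measures reproduce the qualitative values reported for diverse peripheral
  blood (vertex Gini ≈ 0.2–0.3, maximum cluster below 1%): diverse PB
  repertoires are dominated by sequences observed once or twice, so
  acceptance-scale fixtures pair ~5000 clones with ~5000 reads.
- *CLL / LCL*: one dominant clone with frequency drawn from Beta(8,2)
  conditioned on ≥0.60, background clones Dirichlet(1) over the remainder.
  The dominant clone's lineage is concentrated (88–96% unmutated), matching
  the weakly-hypermutated expansions these samples show.

V genes are assigned to clones with Zipf weights over the reference so a
few genes exceed 15% usage while most sit below — the regime the
low-frequency subset analyses are about.

**SHM lineages.** Substitutions only (no indels), so all variants of a
clone are length-matched and the network's distance-1 edges relate them
cleanly; the indel case is deliberately out of scope. A clone carries 0–3
variants (always 0 when `shm_rate` is 0), each with 1 + Poisson(rate ×
length) substitutions at uniform positions. Real SHM hotspot bias (WRCY
motifs) and selection are not modelled, so cluster topology statistics
beyond the Gini/maximum-size summaries should not be over-read.

**RNA vs DNA.** RNA sampling weights each clone by frequency × a
clone-level transcript-burden factor (Gamma with dispersion 2, mean 1,
from a negative-binomial view of per-cell transcript counts with mean 10);
DNA weights by cell frequency and adds, for 30% of clones (configurable),
a nonproductive second-allele rearrangement that only genomic DNA
contains. This is what makes the DNA→RNA overlap percentage sit below
100% and is the package's model of "allelic exclusion" reads.

**Errors.** Substitutions i.i.d. per base (MiSeq-like preset
2.06×10⁻⁴/base; 454-like 7.04×10⁻⁵/base, the substitution-only rate).
The 454-like profile additionally applies ±1 indels per homopolymer run of
length ≥3 with probability 2×10⁻³ per run, putting the homopolymer
contribution on the order of the gap between a combined per-base rate of
~1.7×10⁻⁴ and the substitution-only rate. Quality strings are constant
Phred 38, with an optional fraction of reads at Phred 20 to exercise the
median-quality filter. PCR amplification bias and chimerism are not
modelled.

**Re-amplification.** `amplification_jitter` models an independent
amplification of the same RNA pool as a multinomial draw of 20,000 template
molecules (configurable) — a fresh aliquot contains finitely many
templates, which is the dominant source of extra noise between RT-PCR
repeats relative to re-sequencing the same product. An optional per-gene
lognormal efficiency factor (`gene_bias_cv`) emulates platform/method
capture bias and is used for the cross-platform comparison arm. These two
knobs produce the expected reproducibility ladder: sequencing repeat ≥
re-amplification ≥ cross-platform, at full-table and low-frequency level.

## Read processing

Stages run in a fixed order, each returning a subset of its input
(reported per stage): median-Phred quality filter (strict >32; even-length
median is the mean of the central pair), Ig-similarity retention and
orientation, optional primer trimming, strict length filter (platform
presets: >255 nt for 454, >120 nt for paired MiSeq, >160 nt for
RNA-capture MiSeq), V/J gene assignment, and optional cropping to the
V..J region for capture reads.

**Alignment and E-values.** Segment-vs-read alignments use edlib in infix
mode; terminal indel runs are treated as soft clipping (reads cover
segments partially and vice versa), and the clipped alignment is scored
+1/−2/−2 (match/mismatch/gap). E-values follow Karlin–Altschul,
E = K·m·n·e^(−λS), with the standard ungapped +1/−2 parameters λ=1.28,
K=0.46. Retention requires a V-segment hit at E ≤ 1×10⁻¹⁰ on either
strand (minus-strand hits are reverse-complemented so reads begin with the
V gene); gene assignment requires E ≤ 10⁻²⁰ and takes the best-scoring
segment, breaking score ties lexicographically (deterministic). On the toy
reference these thresholds leave wide score margins, so the exact choice
of aligner/parameters does not flip any test outcome. A lineage variant
with ≥3 substitutions inside the 50 nt toy J can honestly fail the 10⁻²⁰
threshold and is dropped (and counted), not mis-called.

**Primer trimming** searches one forward primer in the first 40 bases and
the reverse primer (as its reverse complement) in the last 40, each with
≤1 mismatch by default (both window and tolerance are explicit config; the
tolerance covers the simulated error rates). Both primers must be found or
the read is discarded. A second pass over already-trimmed reads therefore
discards everything — the both-primer requirement makes primer trimming
deliberately non-idempotent, unlike capture-window cropping, which is.

## Networks and diversity

Vertices are exact-identity deduplicated sequences weighted by read count.
Edges join vertices at Levenshtein distance exactly 1 — substitutions and
single indels — so homopolymer artefacts stay attached to their parent
vertex. Candidate pairs come from deletion-neighborhood hashing (two
sequences at distance 1 must share a single-deletion variant or one must
equal a deletion variant of the other), each candidate verified exactly
with edlib (k=1); the test suite retains an independent brute-force
all-pairs oracle. Clusters are connected components (networkx).

"Cluster size" for the cluster Gini is read mass per cluster by default;
a vertex-count mode is exposed (`cluster_weight="vertices"`) because the
term is ambiguous in the field. The Gini is computed in the sorted
closed form equivalent to Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄); single-element and
perfectly-even inputs give exactly 0; empty or non-positive inputs raise.

## Comparison statistics

Gene-usage regressions go through the origin (slope Σxy/Σx²), since
frequency-vs-frequency comparisons have no intercept; R² is reported as
the squared Pearson correlation of the paired points (the
regression-through-origin R² is non-standard and misleading). Points can
be pooled across matched sample pairs. Low-frequency subsetting keeps
genes strictly below the threshold in *both* members of a pair (symmetric;
default 0.15, the RNA/DNA analysis uses 0.02).

Paired per-gene tests (Wilcoxon signed-rank and paired t) run across
samples, per gene, with Bonferroni correction over genes — the question is
"which genes are differentially captured", not "which samples differ".
All-zero paired differences give p = 1 (logged); exactly constant non-zero
differences drive the t statistic to infinity and are reported as p = 0.

Trimming windows: 5'RACE-like (the `race_length` bases ending at the J
3' end, default 250), CDR3-only (the junction window), and RNA-capture
(149 nt upstream of the V 3' end through 41 nt into the J; these are the
mean-coverage figures, and both parameters are configurable because
rounded variants of them circulate). Reads shorter than a window are kept
at available length; windows that collapse to nothing drop the read with a
warning. The end-to-end replica scales the windows to its shorter toy
amplicons (~260 nt) so each window removes a meaningful region; the
defaults remain the full-scale values.

Sequence overlap between repertoires A and B is the percentage of A's
reads whose exact sequence occurs at least once in B; shared sequences'
frequencies feed the same regression machinery.

## Depth model

Described in the README. Numerical notes: the band bounds are
⌈N·pᵢ·0.9⌉..⌊N·pᵢ·1.1⌋ inclusive, clipped to [0, N]; an empty integer band
gives probability 0, and pᵢ = 0 gives 1 (the band is {0} and p = 0). The
error adjustment p = pᵢ − e·l is exposed but defaults to e = 0: with
realistic per-base rates and any plausible read length, e·l exceeds small
clone proportions outright (e.g. 2×10⁻⁴ × 300 = 0.06 ≫ 4×10⁻⁴), in which
case p clips to 0 with a warning — the reference depth-accuracy results
are only meaningful with the error term treated as negligible. The band
sum anchors one term in log space at the in-band mode, with log C(N,k)
accumulated by `math.fsum` of term logs (float64 `lgamma`-based pmfs have
an ~1e-8 absolute error floor at N ≈ 10⁷), and extends by the exact ratio
recurrence; agreement with an arbitrary-precision oracle is ~1e-10 up to
N = 10⁷. A finite-population hypergeometric mode exists for small
amplified populations; at ~5×10⁷ molecules it is indistinguishable from
the binomial, which is why sampling-with-replacement is the default.

The band probability is *not* monotone in depth for very rare clones: when
the band holds a single integer count, P(X=1 | λ=1) = 0.368 exceeds
P(9 ≤ X ≤ 11 | λ=10) = 0.364. This discreteness effect is real (confirmed
against the arbitrary-precision oracle), so monotonicity is only asserted
where the band spans several counts.

## Problem sizes

Defaults were chosen so the full test suite runs in about a minute and the
demonstration pipeline in ~15 s on one CPU while preserving every
qualitative contrast: toy references of 5–20 V genes, repertoires of
60–5000 clones, read depths of 2000–10,000, gene-usage resampling depths
of 10⁵, and oracle grids to N = 10⁷. The acceptance-scale clonality
fixture (healthy: 5000 clones at 5000 reads; CLL: 60 clones) reproduces
the expected ordering with wide margins (vertex Gini ≈ 0.28 vs 0.91;
maximum cluster ≈ 0.3% vs 76%).

## Known limitations

- The toy germline reference makes gene assignment far easier than
  IMGT-scale references; accuracy numbers do not transfer to real data.
- SHM is substitution-only and position-uniform; class-switch
  recombination, light chains, TCR loci and paired-end merging are out of
  scope.
- PCR amplification bias is represented only as finite-template
  resampling plus optional per-gene efficiency factors, not per-sequence
  efficiency differences.
- The depth model treats reads as i.i.d. draws; it does not model
  amplification bias or chimerism.
- Passing synthetic-data tests demonstrates internal consistency of the
  methods, not field performance on patient repertoires.
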