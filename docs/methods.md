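# Methods

## Model and assumptions

`driverscan` treats each gene as its own case-control experiment.  The
*exonic* test region (union of exons over all transcripts) is compared with
a *local background* — introns plus a 10-kb flank either side of the gene
span, minus the exons of **every** annotated gene of any biotype and minus
user-masked bases.  Locality is the covariate control: replication timing,
expression coupling and chromatin state vary on scales much larger than a
gene plus 20 kb, so the background absorbs them.  The second control is
sequence context: mutational processes are strongly trinucleotide-
dependent, so all simulations reposition mutations only among positions
whose reference 3-mer (centred on the mutated base) matches the mutation's
own.  Contexts are not strand-collapsed: `ATA` and `TAT` are distinct keys,
because the repositioning operates on raw genomic sequence, not on
pyrimidine-normalized signatures.

Two one-sided empirical tests are computed per gene and combined:

- **Recurrence (RE).**  All mutations in exonic ∪ background are
  repositioned independently, with replacement, uniformly within their
  context class of the joint region; the simulated exonic count is compared
  with the observed one.  Because a repositioned mutation affects the count
  only through the exonic/background dichotomy, the simulation is drawn as
  one Binomial per context (n = mutations in that context, p = exonic share
  of matching positions); this is distributionally identical to explicit
  positional draws and O(contexts) per simulation.  An explicit positional
  sampler exists and is exercised by instrumented tests that assert every
  landing stays in the region with its context preserved, and that the two
  samplers agree on the resulting p-value.
- **Functional impact (FI).**  Conditions on exonic placement: the observed
  mean base-level functional score of the exonic mutations is compared with
  means obtained by repositioning each exonic mutation within exonic
  positions of identical context.  Unscored landings are excluded from each
  simulated mean; a simulation in which no landing is scored never counts
  as extreme; a gene whose observed exonic mutations are all unscored gets
  p_FI = 1 and a flag rather than a fabricated score.

Both p-values use the add-one convention p = (1 + k)/(n + 1), which keeps
them strictly positive for the logarithm in Fisher's statistic
T = −2(ln p_RE + ln p_FI), referred to chi-square with 4 df.  A `literal`
mode reproduces the plain k/n ratio (floored at 1/n) for comparison.
Fisher's method assumes the two p-values are independent under the null;
here FI conditions on exonic placement while RE tests placement itself, so
independence holds approximately, and pooled-null simulations show the
combined p-value is uniform (KS p ≈ 0.96 over 400 null genes in the test
conditions).  Benjamini–Hochberg is applied over the tested genes of a
cohort; genes skipped for lack of mutations or an empty (fully
masked/overlapped) background are flagged, excluded from the number of
tests, and reported with q = 1.

Variants retained are single-base substitutions and 1-bp insertions/
deletions, each anchored at a single reference base (the deleted base for
deletions, the base at the insertion point for insertions); that anchor
supplies the trinucleotide context and, when present, the functional score.
Multi-nucleotide variants are dropped and counted.  Mutations from
different samples at the same position remain independent records.

## Randomization-based FDR

`randomize_dataset` moves every mutation to a uniformly chosen position
with identical trinucleotide within ±50 kb on its own chromosome,
excluding the original position whenever an alternative exists (a mutation
whose context is unique in its window, or contains N, stays put).  Sample
labels, alleles, per-chromosome counts and the exact context multiset are
preserved — all asserted by tests.  Running the full analysis on such a
dataset and dividing its hit count by the real hit count gives the
empirical FDR.  The window is read as a half-width (±50 kb); it is exposed
as `--window`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `flank_bp` | 10 000 bp | background flank either side of the gene span |
| `n_simulations` | 10 000 | repositioning simulations per gene and test; the attainable p-value floor is 1/(n+1) |
| `pseudocount` | `add_one` | empirical p-value convention (see above) |
| `window_bp` | 50 000 bp | randomizer half-width |
| coding-potential cutoff | 0.364 | transcripts at or above it mark a gene as protein-coding-like; the gene is dropped |
| q cutoff | 0.1 | BH threshold used in benchmarking and hit lists |
| `MEAN_TIE_TOL` | 1e−12 | absolute tolerance for the ≥ comparison of simulated vs observed means |

10 000 simulations resolve q ≤ 0.1 comfortably for cohorts of a few
hundred genes (floor ≈ 1e−4, two orders below the BH threshold at rank 1)
while keeping a 300-gene cohort run to a few seconds.

## The synthetic generator

The generator builds a study whose null is, by construction, the model the
tests assume: a random-sequence genome (GC fraction 0.41, human-like);
regularly spaced two-exon genes; a score track drawn Normal(10, 4) on
exonic bases and Normal(3, 4) elsewhere, mimicking the exon enrichment of
deleteriousness scores on a PHRED-like scale; and passenger mutations
placed with probability proportional to a trinucleotide signature (flat by
default), with the alternate allele uniform over the three non-reference
bases and samples assigned round-robin.

Default scale: 1 Mb genome, 300 genes of 2 × 500 bp exons (1 kb spliced
length, the GENCODE lncRNA median), 1-kb introns, 20 000 mutations from 50
samples.  That density (0.02 SNV/bp) is close to the pan-cancer WGS
aggregate (~0.015 SNV/bp) and leaves ~20 exonic mutations per gene — the
regime where the integer-count permutation p-value behaves
near-continuously.  With substantially fewer exonic mutations per gene the
RE p-value lattice coarsens and empirical p-values become visibly
conservative (smaller tail mass than nominal, inflated MLFC); that is a
property of count-based permutation tests generally, not of this
implementation.

Driver signal is planted three ways: `burden` adds context-respecting
exonic mutations until the expected exonic count is multiplied by
`fold_effect`; `impact` repositions the gene's existing exonic mutations
with weight ∝ exp(score/τ) (τ = 1 by default, a strong preference on the
default score scale) without changing the count; `both` does both.

What the generator does **not** emulate: real covariate structure
(replication timing, expression-coupled repair), sequence composition
heterogeneity (CpG islands, repeats), copy-number and structural variation,
clustered hypermutation (kataegis), signature heterogeneity across samples,
and annotation complexity (overlapping isoforms, multi-chromosome
assemblies beyond what tests construct directly).  Passing tests therefore
demonstrate internal statistical correctness and calibration under the
stated null — not performance on real tumour genomes.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GTF is converted on read,
  BED read natively.  Region arithmetic is exact base-pair set algebra,
  checked against a per-base bit-vector oracle.
- Per-gene RNG streams are derived from (seed, CRC-32 of gene id, test
  index), and mutations are canonically sorted before per-mutation draws,
  so results are invariant to gene order and input row order, and
  identical seeds give byte-identical output tables.
- The overlap filter against protein-coding genes uses gene spans by
  default (`overlap_mode="exon"` available); the filter exempts
  protein-coding genes themselves.  Exons of *all* parsed genes — including
  filtered-out ones — are excluded from every background.
- Flanks are clipped silently at chromosome ends.  A mutation whose context
  has no candidate position stays at its original position in every
  simulation and the gene is flagged.
- Ties on simulated counts use integer ≥; ties on simulated means use an
  absolute tolerance of 1e−12.
- The calibration metric is mean |log2(observed/expected)| over sorted
  p-values paired with the uniform quantiles i/n (NA p-values discarded
  first).  A `literal` variant reporting the plain mean |observed/expected|
  ratio is provided for comparison; it equals 1, not 0, under perfect
  calibration, which is why the logarithmic form is the default.
- In benchmarking, false negatives are counted over tested genes only;
  truth genes absent from the annotation do not enter the denominator.
  When an explicit negative set is supplied, predictions outside
  truth ∪ negatives are ignored.

## Known limitations

- Fisher integration is only approximately valid under dependence between
  the two component tests; under strong alternatives they are positively
  dependent, which affects power accounting but not null calibration.
- Empirical p-values cannot go below 1/(n_simulations + 1); cohorts much
  larger than ~10⁴ genes need more simulations for BH resolution at small
  q.
- At q ≤ 0.1, BH admits on the order of 0.1 × (number of discoveries)
  false calls by design; with ~10 true drivers discovered, one or two null
  genes in the hit list is the expected behaviour, and the
  randomization-based empirical FDR is the appropriate cohort-level check.
- The FI test is only as good as the score track: sparse coverage shrinks
  the scored-mutation set, and wholly unscored genes fall back to p_FI = 1.
- VCF ingestion requires a syntactically valid header (pysam); MAF-lite
  TSV is the primary interchange format.
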