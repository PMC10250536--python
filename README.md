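# driverscan

Discovery of genomic elements under positive selection in tumour cohorts —
lncRNA genes in particular, though the statistic is biotype-agnostic — from
maps of somatic single-nucleotide variants and 1-bp indels.

Cancer driver elements betray themselves through two signals: an elevated
**mutational burden** (more mutations than the local neutral rate allows)
and elevated **functional impact** (the mutated bases matter more than
random exonic bases would).  Both must be judged against a background that
respects the strong context-dependence of mutational processes, otherwise
replication timing, expression and chromatin covariates masquerade as
selection.  `driverscan` tests each gene with two empirical permutation
tests calibrated by trinucleotide-preserving repositioning, combines them
with Fisher's method, and controls the false discovery rate across the
cohort with Benjamini–Hochberg.

## The statistic

For each gene, the *exonic* region is the union of its exons over all
transcripts, and the *background* is introns plus 10 kb up/downstream,
minus every annotated gene's exons and any masked (low-mappability/gap)
bases.

**Recurrence (RE).** Every mutation in exonic ∪ background is repositioned,
independently and uniformly, among positions of that joint region sharing
its reference trinucleotide (the 3-mer centred on the mutated base).  With
`n` simulations,

    p_RE = (1 + #{simulated exonic count ≥ observed}) / (n + 1)

**Functional impact (FI).** The observed statistic is the mean base-level
functional score (CADD-style) of the exonic mutations; simulations
reposition each exonic mutation within exonic positions of identical
context:

    p_FI = (1 + #{simulated mean score ≥ observed}) / (n + 1)

**Integration.** `T = −2(ln p_RE + ln p_FI)` is referred to a chi-square
distribution with 4 degrees of freedom (`p = (1 + T/2)·e^{−T/2}`), and
combined p-values are BH-adjusted to q-values over the tested genes.

Diagnostics follow standard practice for driver methods: QQ comparison of
observed p-values against the uniform expectation `i/n`, the mean absolute
log2 fold change (MLFC) between them, precision/sensitivity/F1 against
curated truth sets, and an empirical FDR computed by re-running the whole
analysis on a dataset in which every mutation is moved to a random
context-matched position within ±50 kb.

## Worked example

The package ships a synthetic-study generator, so the full pipeline runs
without any downloads.  Here a 200-kb genome with 50 two-exon genes gets
~4000 signature-drawn passenger mutations plus two planted drivers: G0007
with 8-fold exonic burden, and G0031 with both extra burden and
score-biased placement:

```python
from driverscan import SyntheticSpec, generate_cohort, DriverDiscoveryModel

spec = SyntheticSpec(genome_length=200_000, n_genes=50, n_mutations=4_000, seed=11,
                     driver_plan=[("G0007", "burden", 8.0), ("G0031", "both", 6.0)])
ds = generate_cohort(spec)
model = DriverDiscoveryModel(ds.mutations, ds.genes, ds.genome,
                             scores=ds.scores, all_exons=ds.all_exons)
results = model.fit(n_simulations=10_000, seed=1)
print(results.summary(top=5))
```

```
Driver discovery results
============================================================
genes tested:      50 / 50
mutations:         4240
simulations:       10000 (seed 1)
hits (q <= 0.1): 2
MLFC (combined p): 0.6352 over 50 genes
------------------------------------------------------------
gene_id  n_exonic_obs  n_background_obs  mean_fi_obs      p_re      p_fi  fisher_T  p_combined   q_value
  G0031           121               279        22.07 9.999e-05 9.999e-05     36.84   1.942e-07 9.708e-06
  G0007           158               309        9.686 9.999e-05    0.9332     18.56   0.0009592   0.02398
  G0004            26               303        11.51   0.08659    0.0287        12     0.01739    0.2898
  G0030            26               282         11.3   0.06129    0.1114     9.974     0.04087     0.406
  G0003            29               303        10.52    0.0468    0.1737     9.625     0.04724     0.406
```

Both planted drivers are recovered at q ≤ 0.1 and no null gene is called.
G0031 is extreme on both axes (121 exonic mutations against a local
expectation near 20; mean score 22.1 against an exonic mean of 10), while
G0007's signal is burden-only, so its p_FI stays null (0.93).  The elevated
MLFC here reflects the planted drivers sitting in a 50-gene table; on a
pure null cohort it is ≈ 0.08 (see below).  `results.plot_qq()` draws the
QQ panel, `results.to_tsv("results.tsv")` writes the table.

The same analysis is available from the shell:

```sh
driverscan simulate --outdir sim/            # synthetic study (YAML-configurable)
driverscan run --muts sim/muts.maf.gz --gtf sim/genes.gtf --fasta sim/ref.fa \
               --scores sim/scores.tsv.gz --nsim 10000 --seed 1 --out results.tsv
driverscan randomize --muts sim/muts.maf.gz --fasta sim/ref.fa --out rand.maf
driverscan benchmark --results results.tsv --truth sim/truth.txt --out bench.tsv
```

Every subcommand writes a JSON manifest (inputs' SHA-256, configuration,
counts) next to its output; identical seeds reproduce outputs
byte-identically.

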