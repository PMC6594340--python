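# Methods

## Abundance model

The unit of quantification is the biosynthetic gene cluster (BGC). A read
contributes to a cluster's abundance only when its single best alignment
(top hit) lands on one of the cluster's *biosynthesis* genes. Gene
classification is a property of the catalog, computed once, not per read:

- a gene is **biosynthesis** when at least one Pfam domain hit from the
  biosynthesis list survives the domain E-value cutoff (default 0.01) and no
  surviving hit comes from the nonbiosynthesis list;
- any surviving nonbiosynthesis hit **vetoes** the gene. The
  nonbiosynthesis list exists to keep transport, regulation and
  housekeeping genes inside cluster boundaries from inflating abundances,
  so the veto is the conservative resolution of a mixed domain content;
- genes with no surviving hits are **unclassified** and never counted.
  Pfam accessions are matched with version suffixes stripped
  (`PF00501.28` ≡ `PF00501`).

Top-hit selection is maximal bit score, ties broken by minimal E-value and
then lexicographically smallest protein id. The tie-break is arbitrary but
total, which makes assignment tables byte-identical across input orderings —
a reproducibility property the test suite asserts.

Counts are normalized per sample to counts-per-million of the sample's
total (post-QC, pre-alignment) read count: N = F·10⁶/Σ. There is no
length normalization: clusters differ in gene count and gene length, so N
is comparable across samples within a cluster (the use all downstream rank
statistics make of it) but not across clusters.

## Retention filter

A cluster enters the abundance matrix when both hold:

- **gene detection**: at least `min_gene_fraction` (default 0.5) of its
  biosynthesis genes have ≥ 1 assigned read anywhere in the cohort. This is
  a cohort-wide union, making retention a property of the cluster rather
  than of individual cells;
- **sample support**: strictly more than `min_samples` (default 10) samples
  carry at least `min_reads` (default 10) reads for it.

Zero cells of retained clusters are imputed with 0.01 counts-per-million
(configurable), and the imputation mask is carried alongside the values.
Imputation happens after retention; unretained clusters are removed, not
imputed. The imputed value is deliberately below any observable normalized
count at realistic library sizes, so imputed cells form the bottom tied
block of every rank statistic rather than interleaving with real
observations.

## Association statistics

Spearman's rank correlation with average ranks for ties; two-sided p-values
from the t approximation with n−2 degrees of freedom. An exact permutation
p-value (full enumeration) is available for n ≤ 10, where the t
approximation is at its weakest. Constant vectors have no defined rank
correlation; they are reported with an `undefined_correlation` flag and
excluded from the multiple-testing family, never returned as silent NaN.

Benjamini–Hochberg adjustment is the standard step-up
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1, applied per family: all tested
clusters of one catalog form one family, the phyla of one taxonomic table
another. A perfect monotone relation yields p = 0 under the t
approximation; for the step-up this is clamped to the smallest positive
float, which leaves every q-value unchanged to machine precision.

The per-sample **mean abundance** statistic is the arithmetic mean over all
retained clusters, imputed cells included, correlated against BMI with the
same Spearman contract. Association tables are sorted by p ascending with
ties broken by feature id, and report both p and q.

## Synthetic cohorts

The generator emulates the input bundle of a fecal-metagenome BGC survey
and is the package's validation instrument. Design choices, with defaults:

- **Cohort**: 150 samples. BMI from a two-component normal mixture,
  lean N(23.5, 2.0²) and obese N(33, 4²) weighted 123:169 — the weights
  mirror a published lean/obese cohort split; means and SDs are generator
  choices for a realistic adult range. Values are clipped to [15, 60].
- **Catalog**: 100 clusters of 3–8 genes, 75% biosynthesis genes per
  cluster under a 1-protein-per-gene convention; the remaining genes
  alternate nonbiosynthesis/unclassified. Protein sequences are random
  60-mers — alignment is out of scope, so sequences are placeholders.
- **Planted effects**: a cluster's dependence on BMI is a Gaussian copula:
  z = r·z_BMI + √(1−r²)·ε with z_BMI the normal scores of the BMI ranks and
  r = 2·sin(πρ_s/6), so the *population* Spearman of the latent equals the
  target ρ_s exactly. Default: 5 clusters at ρ_s = 0.4.
- **Counts**: the latent is pushed through a zero-inflated
  negative-binomial quantile link. Per-cluster means are log-uniform on
  [20, 80]; dispersion k = 2 (variance μ + μ²/2 — metagenomic counts are
  overdispersed, so a Poisson link would be too clean). The zero inflation
  (`sparsity`, default 0.2) is the point mass at the *bottom* of the link:
  a cluster is absent from a sample with probability ≥ sparsity, and
  absences fall in the samples where the latent abundance is lowest. This
  keeps the link monotone in the latent, so the planted population Spearman
  carries through to the observable counts (independent per-cell dropout
  would attenuate a planted 0.4 to ≈ 0.25 and the generator would no longer
  produce the condition it claims). Scipy's discrete ppf returns −1 at
  probability exactly 0, hence the small positive lower clip.
- **Phylum effects** are planted the same way, against the normal scores of
  the designated cluster's *observed* counts (not its latent), again so the
  target correlation refers to a quantity the pipeline can actually
  measure. Profiles are log-normal compositions renormalized to 100% per
  sample; closure attenuates planted correlations mildly (≈ 0.35 → 0.33 in
  calibration runs).
- **Hit files** contain exactly the alignment lines needed to reproduce the
  intended count matrix — each counted read one qualifying top hit on a
  biosynthesis gene, distributed round-robin over the cluster's genes —
  plus deliberate negatives: suboptimal secondary hits, reads whose top hit
  is a nonbiosynthesis gene, and one sub-threshold line per sample. The
  round-robin keeps gene detection at 1 for any cluster with enough reads
  and makes generation deterministic. FASTQ output (75 bp placeholder
  reads) is optional since the alignment step itself is out of scope.

Everything derives from one `numpy` SeedSequence, so a fixed spec and seed
reproduce byte-identical bundles (hash-checked in the tests).

What the generator does **not** emulate: read sequences and alignment
scoring (bit scores are constants), catalog redundancy across genomes,
compositional coupling between cluster abundances, library-size/abundance
confounding, and BMI measurement error. Passing tests therefore validate
the bookkeeping, the statistics and the recovery properties of the
pipeline — not the behavior of DIAMOND, hmmscan or MetaPhlAn on real reads.

## Validation sizes

The test suite runs the full file-based pipeline on 150-sample cohorts for
planted-signal recovery (10 seeds), in-memory cohorts for the global-null
false-discovery check (20 seeds), and 20 randomized small specs
(6–16 samples) for the exact generator/pipeline count roundtrip; oracle
checks use 200 random matrices up to 20×20 and exhaustive rank-permutation
enumeration up to n = 8. These sizes were chosen to make the checks sharp
at interactive runtimes.

## Degenerate inputs and numerical notes

- Empty FASTA/mapping, duplicate protein ids, mapping/FASTA mismatches:
  hard errors naming the offender.
- Malformed BLAST-tab lines are counted and reported, never silently
  skipped; non-numeric numeric fields abort with the line number.
- A sample with zero total reads cannot be normalized: hard error.
- An empty retention set is a valid outcome (logged), as is an association
  table whose every feature is flagged constant.
- Samples missing BMI are dropped pairwise with a logged count; association
  requires ≥ 3 overlapping samples.
- `filter_bgcs` uses a strict `>` on sample support by default (a
  `strict_sample_inequality` switch flips it to ≥).

## Known limitations

- Abundances are not length-normalized; cross-cluster comparisons of N are
  not meaningful.
- The BH family is all tested features of one table; no hierarchical or
  cross-catalog correction.
- The t-approximate Spearman p-value is anti-conservative for very small n;
  use the exact option there.
- One protein = one gene is assumed throughout; catalogs with split genes
  need their mapping collapsed beforehand.
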