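# bgcquant

Quantification of secondary-metabolite **biosynthetic gene clusters (BGCs)**
in shotgun metagenomes, and association of their abundance with host
phenotype (BMI) and gut community composition.

Microbes shape their community by secreting secondary metabolites (SMs) —
antibiotics, siderophores, quinones — whose biosynthesis is encoded in
physically clustered genes (BGCs). `bgcquant` takes per-sample read
alignments against a BGC protein catalog and turns them into per-sample
cluster abundances and rank-correlation association tables, the analysis a
microbiome group would run to ask *which gene clusters track obesity?*

## What it computes

Given reads aligned to a catalog of BGC proteins (DIAMOND/BLAST tabular
output) and Pfam domain annotations of the catalog (HMMER domtblout):

1. **QC** — reads trimmed to their first 70 bp; shorter reads dropped.
2. **Assignment** — alignment hits filtered at E ≤ 1e-05, one deterministic
   top hit per read, validated against Pfam-defined *biosynthesis* domains
   (hmmscan E ≤ 0.01; nonbiosynthesis domains veto, to keep housekeeping and
   transport genes from contaminating the signal).
3. **Quantification** — per sample and cluster, F = number of reads on the
   cluster's biosynthesis genes. Clusters are retained when ≥ 50% of their
   biosynthesis genes are detected cohort-wide and more than 10 samples
   carry ≥ 10 reads. Retained counts are normalized to counts-per-million,

       N = F × 10⁶ / Σ_total ,

   and a retained cluster absent from a sample is imputed at 0.01.
4. **Association** — per-cluster Spearman ρ against BMI with
   Benjamini–Hochberg correction; the per-sample mean abundance vs BMI; and
   a chosen cluster's abundance against phylum-level MetaPhlAn profiles.

A seeded synthetic-cohort generator (`bgcquant.simulate`) produces complete
input bundles — catalog FASTA + mapping, Pfam lists, domtblout, per-sample
hit tables, FASTQ, totals, BMI metadata, taxonomic profiles — with *planted*
monotone BMI associations realized through a Gaussian copula and a
zero-inflated negative-binomial count link, so the whole pipeline can be
validated against known ground truth.

## Worked example

```bash
bgcquant simulate --out demo/bundle --seed 7
cat > demo/cfg.yaml <<EOF
catalog_fasta: demo/bundle/catalog.faa
catalog_mapping: demo/bundle/catalog_mapping.tsv
annotations: demo/bundle/annotations.tsv
pfam_biosynthesis: demo/bundle/pfam_biosynthesis.txt
pfam_nonbiosynthesis: demo/bundle/pfam_nonbiosynthesis.txt
domtblout: demo/bundle/domains.domtblout
hits_dir: demo/bundle/hits
totals: demo/bundle/totals.tsv
metadata: demo/bundle/metadata.tsv
tax_profile: demo/bundle/tax_profile.tsv
EOF
bgcquant run-all --config demo/cfg.yaml --out demo/out
```

prints

```
retained 100 clusters; mean abundance vs BMI rho=0.0439 p=0.594; outputs in demo/out
```

and `demo/out/associations_bmi.tsv` begins

```
genome_id   cluster_id  rho       p_value      q_value      n    note  best_hit
641000004   160000004   0.359429  6.26754e-06  0.000626754  150        Organism sp. 004
641000003   160000003   0.327467  4.30536e-05  0.00215268   150        Organism sp. 003
641000000   160000000   0.304997  0.000147638  0.00371836   150        Organism sp. 000
```

The five clusters this default cohort plants at population Spearman ρ = 0.4
occupy the top five rows, each with q < 0.01; the remaining 95 null clusters
fall below them (the mean-abundance correlation is near zero here because
only 5 of 100 clusters carry signal). `demo/out/` also contains the
abundance matrix with its imputation mask, the per-sample mean abundance,
the phylum association table, a run log, and the fully resolved
configuration, so rerunning the same config reproduces identical outputs.

The library API mirrors the CLI: `load_catalog`, `classify_gene`,
`qc_trim_reads`, `parse_blast_tab`, `select_top_hit`, `assign_reads`,
`parse_domtblout`, `count_bgc_reads`, `filter_bgcs`, `normalize`,
`spearman`, `bh_adjust`, `associate_bmi`, `mean_abundance_stat`,
`associate_taxa`, `generate_cohort`, `roundtrip_check`.

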